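"""In-memory genome sequences and small sequence utilities."""

from __future__ import annotations

from typing import Mapping

from Bio import SeqIO

from .intervals import GenomicInterval

__all__ = ["Genome", "reverse_complement", "gc_fraction"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction over non-N bases; 0.0 for an all-N or empty sequence."""
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (s.count("G") + s.count("C")) / acgt


class Genome:
    """A multi-chromosome nucleotide sequence store.

    Sequences are held uppercased (soft-masking is ignored for scanning).
    Suited to the simulated genomes and region-scale extracts this package
    works with; it is not a memory-mapped reader for full mammalian genomes.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def fetch(self, interval: GenomicInterval, clip: bool = False) -> str:
        """Sequence of ``interval``; minus-strand intervals are reverse
        complemented. With ``clip`` the span is truncated at chromosome ends,
        otherwise out-of-bounds spans raise."""
        seq = self._seqs.get(interval.chrom)
        if seq is None:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        start, end = interval.start, interval.end
        if clip:
            start, end = max(0, start), min(len(seq), end)
        elif start < 0 or end > len(seq):
            raise ValueError(
                f"{interval.chrom}:{start}-{end} outside chromosome "
                f"(length {len(seq)})"
            )
        sub = seq[start:end]
        if interval.strand == "-":
            sub = reverse_complement(sub)
        return sub

    def gc(self, interval: GenomicInterval) -> float:
        return gc_fraction(self.fetch(interval))
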