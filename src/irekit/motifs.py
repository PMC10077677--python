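"""IUPAC degenerate motif scanning and motif-frequency statistics.

The AP-1 and ETS transcription-factor families are represented by degenerate
IUPAC consensus codes (family consensus AP-1 = TKASTMA, ETS = VVGGAWVY) plus
per-factor codes shipped in :data:`MOTIF_REGISTRY`. Scanning reports every
(possibly overlapping) sliding-window match; the per-kilobase motif
frequency of a region is f = 1000 * c / s for c matches in s bases.

Strand handling: TKASTMA is its own IUPAC reverse complement, so AP-1 counts
are strand-invariant; VVGGAWVY is not, so the ``strand_mode`` flag matters
for ETS counts. The default, ``both_dedup``, counts unique forward-coordinate
windows matched on either strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .genome import Genome
from .intervals import AnnotationSet, GenomicInterval

__all__ = [
    "IUPAC",
    "MotifPattern",
    "MotifHits",
    "MOTIF_REGISTRY",
    "AP1",
    "ETS",
    "scan_motif",
    "motif_frequency",
    "classify_motif_groups",
    "gc_matched_background",
    "motif_presence_enrichment",
    "relative_overlap_ratio",
    "EnrichmentResult",
    "OverlapRatioCurve",
    "registry_table",
]

# degenerate nucleotide alphabet; a sequence N only satisfies a pattern N
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC degenerate motif code of length >= 4."""

    name: str
    family: str  # "AP-1", "ETS" or "other"
    iupac: str

    def __post_init__(self) -> None:
        if len(self.iupac) < 4:
            raise ValueError("motif code must be at least 4 letters")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letter(s) {sorted(bad)} in {self.iupac!r}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def regex(self) -> "re.Pattern":
        # lookahead so overlapping windows are all reported
        body = "".join(f"[{IUPAC[c]}]" for c in self.iupac)
        return re.compile(f"(?=({body}))")

    def reverse_complement(self) -> "MotifPattern":
        rc = "".join(_IUPAC_COMPLEMENT[c] for c in reversed(self.iupac))
        return MotifPattern(self.name, self.family, rc)

    def is_palindromic(self) -> bool:
        return self.iupac == self.reverse_complement().iupac


@dataclass
class MotifHits:
    """Match positions of one pattern in one sequence.

    ``positions`` holds unique (forward-coordinate offset, strand) pairs;
    ``frequency`` is the per-kb statistic 1000 * count / length.
    """

    pattern: MotifPattern
    sequence_length: int
    positions: list[tuple[int, str]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.positions)

    @property
    def frequency(self) -> float:
        return motif_frequency(self.count, self.sequence_length)


# Family consensus codes plus the per-factor codes used for the family-level
# frequency comparisons.
AP1 = MotifPattern("AP-1", "AP-1", "TKASTMA")
ETS = MotifPattern("ETS", "ETS", "VVGGAWVY")

_ETS_FACTORS = {
    "EHF": "DNVMGGAAR",
    "ELF1": "SCGGAAGY",
    "ELF3": "WNVMGGAARY",
    "ELF4": "VMGGAAG",
    "ELF5": "WNVMGGAAGT",
    "ERG": "CMGGAARY",
    "ETS1": "RVMGGAWRY",
    "ETV1": "CMGGAWG",
    "ETV2": "VMGGAWR",
    "ETV4": "SMGGAWRB",
    "FLI1": "VMGGAWR",
    "GABPA": "VMGGAAG",
    "PU.1": "DVRGGAAGTG",
    "SPIB": "DWDVRGAAVYS",
}
_AP1_FACTORS = {
    "ATF3": "VTKANTCAB",
    "BATF": "TKASTMA",
    "FOS": "TKANTYA",
    "FRA1": "VTKANTMAB",
    "FRA2": "TKWSYMA",
    "JUN": "TGASTCA",
    "JUNB": "TKASTCA",
}

MOTIF_REGISTRY: dict[str, MotifPattern] = {
    **{n: MotifPattern(n, "ETS", c) for n, c in _ETS_FACTORS.items()},
    **{n: MotifPattern(n, "AP-1", c) for n, c in _AP1_FACTORS.items()},
    AP1.name: AP1,
    ETS.name: ETS,
}


def registry_table() -> pd.DataFrame:
    return pd.DataFrame(
        [(p.name, p.family, p.iupac) for p in MOTIF_REGISTRY.values()],
        columns=["name", "family", "iupac"],
    )


def scan_motif(
    sequence: str,
    pattern: MotifPattern,
    strand_mode: str = "both_dedup",
) -> MotifHits:
    """All sliding-window matches of ``pattern`` in ``sequence``.

    ``forward`` scans the given strand only. ``both_dedup`` (default) counts
    unique forward-coordinate windows matching on either strand (a window
    matching both strands counts once, recorded as '+'). ``both_sum`` counts
    the two strands independently, so a double-matching window counts twice.
    Lowercase bases are uppercased; a sequence N fails every non-N pattern
    position.
    """
    if strand_mode not in ("forward", "both_dedup", "both_sum"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    seq = sequence.upper()
    fwd = [m.start() for m in pattern.regex.finditer(seq)]
    if strand_mode == "forward":
        positions = [(i, "+") for i in fwd]
        return MotifHits(pattern, len(seq), positions)
    # a reverse-strand match at forward window offset i corresponds to a
    # forward-strand match of the reverse-complemented code at i
    rev = [m.start() for m in pattern.reverse_complement().regex.finditer(seq)]
    if strand_mode == "both_sum":
        positions = [(i, "+") for i in fwd] + [(i, "-") for i in rev]
    else:
        fwd_set = set(fwd)
        positions = sorted(
            [(i, "+") for i in fwd] + [(i, "-") for i in rev if i not in fwd_set]
        )
    return MotifHits(pattern, len(seq), positions)


def motif_frequency(c: int, s: int) -> float:
    """Per-kilobase motif frequency f = 1000 * c / s."""
    if s <= 0:
        raise ValueError("sequence size s must be > 0")
    if c < 0:
        raise ValueError("count c must be >= 0")
    return 1000.0 * c / s


def classify_motif_groups(
    ires: Sequence[GenomicInterval],
    genome: Genome,
    ap1: MotifPattern = AP1,
    ets: MotifPattern = ETS,
    strand_mode: str = "both_dedup",
) -> tuple[list[str], dict[str, int]]:
    """Label each region by family-motif presence: "AP-1 only", "ETS only",
    "both", or "neither"; returns (labels, group counts)."""
    labels = []
    counts = {"AP-1 only": 0, "ETS only": 0, "both": 0, "neither": 0}
    for iv in ires:
        seq = genome.fetch(iv)
        has_ap1 = scan_motif(seq, ap1, strand_mode).count >= 1
        has_ets = scan_motif(seq, ets, strand_mode).count >= 1
        if has_ap1 and has_ets:
            label = "both"
        elif has_ap1:
            label = "AP-1 only"
        elif has_ets:
            label = "ETS only"
        else:
            label = "neither"
        labels.append(label)
        counts[label] += 1
    return labels, counts


def gc_matched_background(
    pool: Sequence[GenomicInterval],
    targets: Sequence[GenomicInterval],
    genome: Genome,
    n: int,
    gc_tolerance: float = 0.02,
    seed: int = 0,
    gc_match: bool = True,
) -> list[GenomicInterval]:
    """Sample ``n`` pool regions whose GC composition matches the targets.

    Regions are binned by GC fraction (bin width 2 * ``gc_tolerance``, so a
    selected region sits within ±tolerance of some target's GC); the target
    bin histogram is reproduced in the sample (largest-remainder
    apportionment), without replacement and reproducibly under ``seed``.
    With ``gc_match=False`` the pool is sampled uniformly instead (used for
    random-promoter controls).
    """
    rng = np.random.default_rng(seed)
    pool = list(pool)
    if not gc_match:
        if n > len(pool):
            raise ValueError("pool smaller than requested sample")
        idx = rng.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in sorted(idx)]

    width = 2.0 * gc_tolerance
    def bin_of(gc: float) -> int:
        return int(min(gc, 1.0 - 1e-9) / width)

    target_bins = np.array([bin_of(genome.gc(iv)) for iv in targets])
    pool_bins: dict[int, list[int]] = {}
    for i, iv in enumerate(pool):
        pool_bins.setdefault(bin_of(genome.gc(iv)), []).append(i)

    bins, counts = np.unique(target_bins, return_counts=True)
    quota = n * counts / counts.sum()
    take = np.floor(quota).astype(int)
    rem = quota - take
    for j in np.argsort(-rem)[: n - take.sum()]:
        take[j] += 1

    chosen: list[int] = []
    for b, t in zip(bins, take):
        avail = pool_bins.get(int(b), [])
        if t > len(avail):
            lo, hi = b * width, (b + 1) * width
            raise ValueError(
                f"insufficient pool regions in GC bin [{lo:.2f}, {hi:.2f}): "
                f"need {t}, have {len(avail)}"
            )
        if t:
            chosen.extend(rng.choice(avail, size=int(t), replace=False))
    return [pool[i] for i in sorted(chosen)]


@dataclass
class EnrichmentResult:
    """Presence-based motif enrichment of foreground vs background regions."""

    motif: str
    fore_present: int
    fore_total: int
    back_present: int
    back_total: int
    odds_ratio: float
    p_value: float


def motif_presence_enrichment(
    fore: Sequence[GenomicInterval],
    back: Sequence[GenomicInterval],
    genome: Genome,
    pattern: MotifPattern,
    strand_mode: str = "both_dedup",
) -> EnrichmentResult:
    """Fisher exact test (two-sided) on the 2x2 motif presence table.

    A simplified, fully specified substitute for a known-motif enrichment
    tool: it tests presence/absence against a (typically GC-matched)
    background and makes no log-odds model claims. The odds ratio uses a
    Haldane 0.5 correction when any cell is zero.
    """
    if not fore or not back:
        raise ValueError("foreground and background must be non-empty")
    fp = sum(
        scan_motif(genome.fetch(iv), pattern, strand_mode).count >= 1 for iv in fore
    )
    bp = sum(
        scan_motif(genome.fetch(iv), pattern, strand_mode).count >= 1 for iv in back
    )
    a, b = fp, len(fore) - fp
    c, d = bp, len(back) - bp
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oddsr = (a * d) / (b * c)
    return EnrichmentResult(pattern.name, fp, len(fore), bp, len(back), oddsr, p)


@dataclass
class OverlapRatioCurve:
    """Relative overlapping ratio r_i = n_i / n_0 across motif-frequency bins
    (bin 0 = motif-free sequences), with a shuffled-peak control."""

    bin_edges: list[float]
    n: list[int]
    r: list[float]
    n_shuffled: list[int]
    r_shuffled: list[float]


def _overlap_counts(
    sequences: Sequence[GenomicInterval],
    bin_index: np.ndarray,
    n_bins: int,
    peaks: AnnotationSet,
) -> list[int]:
    out = [0] * n_bins
    for iv, b in zip(sequences, bin_index):
        if peaks.overlapping(iv):
            out[int(b)] += 1
    return out


def relative_overlap_ratio(
    sequences: Sequence[GenomicInterval],
    frequencies: Sequence[float],
    peaks: AnnotationSet,
    bins: Sequence[float],
    chrom_sizes: dict[str, int],
    seed: int = 0,
) -> OverlapRatioCurve:
    """Peak-overlap enrichment as a function of motif frequency.

    Sequences (typically random 1 kb regions) are binned by motif frequency:
    bin 0 holds motif-free sequences (f == 0); positive frequencies fall into
    ``bins`` (ascending right edges; the last bin is open-ended). n_i counts
    bin-i sequences overlapping >= 1 peak and r_i = n_i / n_0. A shuffled
    control repositions every peak uniformly on its own chromosome
    (length-preserving, seeded) and recomputes the curve.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if len(freqs) != len(sequences):
        raise ValueError("frequencies must align with sequences")
    edges = list(bins)
    n_bins = len(edges) + 2  # zero bin + len(edges)+1 positive bins
    bin_index = np.where(freqs == 0, 0, 1 + np.digitize(freqs, edges))

    n = _overlap_counts(sequences, bin_index, n_bins, peaks)
    if n[0] == 0:
        raise ValueError("empty reference bin: no motif-free sequence overlaps")

    rng = np.random.default_rng(seed)
    shuffled = []
    for pk in peaks:
        size = chrom_sizes[pk.chrom]
        length = len(pk)
        start = int(rng.integers(0, max(1, size - length)))
        shuffled.append(GenomicInterval(pk.chrom, start, start + length, pk.name))
    n_shuf = _overlap_counts(
        sequences, bin_index, n_bins, AnnotationSet(shuffled, label="shuffled")
    )
    r = [ni / n[0] for ni in n]
    n0s = n_shuf[0] if n_shuf[0] > 0 else np.nan
    r_shuf = [ni / n0s for ni in n_shuf]
    return OverlapRatioCurve(edges, n, r, n_shuf, r_shuf)
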