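"""Readers and writers for the plain-text formats the pipeline consumes.

BED is 0-based half-open; GTF is 1-based inclusive and converted to the
internal 0-based convention on read (plus-strand TSS = start, minus-strand
TSS = end).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import gffutils
import pandas as pd

from .intervals import GeneModel, GenomicInterval

__all__ = [
    "read_bed",
    "write_bed",
    "read_gtf_genes",
    "write_gtf_genes",
    "read_ortholog_table",
    "write_ortholog_table",
]


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/4/6 (tab-separated, no header) into intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("BED requires at least 3 columns")
    out = []
    for row in df.itertuples(index=False):
        name = row[3] if len(row) > 3 else None
        strand = row[5] if len(row) > 5 else "."
        out.append(
            GenomicInterval(row[0], int(row[1]), int(row[2]), name=name, strand=strand)
        )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, scores=None) -> None:
    """Write BED6 (BED4 when no interval carries a strand)."""
    intervals = list(intervals)
    with_strand = any(iv.strand != "." for iv in intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name or f"region_{i}"]
            if with_strand or scores is not None:
                fields.append(str(scores[i]) if scores is not None else "0")
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def read_gtf_genes(path) -> list[GeneModel]:
    """Extract gene-level records from a GTF into :class:`GeneModel`."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        if feat.strand == "-":
            tss = feat.end - 1  # 1-based inclusive end -> 0-based offset
        else:
            tss = feat.start - 1
        genes.append(GeneModel(gene_id, feat.seqid, feat.strand or "+", tss))
    return genes


def write_gtf_genes(genes: Sequence[GeneModel], path, gene_length: int = 1000) -> None:
    """Emit one gene record per GeneModel (gene body drawn downstream of the
    TSS with a nominal length, which is sufficient for TSS-based analyses)."""
    with open(path, "w") as fh:
        for g in genes:
            if g.strand == "+":
                start1, end1 = g.tss + 1, g.tss + gene_length
            else:
                start1, end1 = max(1, g.tss + 2 - gene_length), g.tss + 1
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "irekit",
                        "gene",
                        str(start1),
                        str(end1),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_ortholog_table(path) -> pd.DataFrame:
    """TSV with columns query_gene_id, target_gene_id, pct_identity."""
    df = pd.read_csv(path, sep="\t")
    required = {"query_gene_id", "target_gene_id", "pct_identity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
    return df


def write_ortholog_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
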