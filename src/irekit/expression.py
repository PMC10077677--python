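"""TPM quantification, simplified differential expression, and the scRNA
cell-type assignment of injury-induced genes.

Differential expression uses median-of-ratios size factors and the same
conditional exact NB test as the ChIP stage; it fills the role a dedicated
count-model package would normally play, with fully stated internals. The
downstream single-cell step normalizes each cell as log1p(1e4 * count /
cell_total) and assigns each significantly induced gene to the cell type
with the largest injured-vs-uninjured fold change of its mean normalized
expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _stats

__all__ = [
    "tpm",
    "ExpressionTable",
    "DEResult",
    "differential_expression",
    "CellTypeAssignment",
    "assign_cell_types",
    "CANONICAL_CELL_TYPES",
]

INJURED = "injured"
UNINJURED = "uninjured"

CANONICAL_CELL_TYPES = (
    "cardiomyocyte",
    "endothelial cell",
    "fibroblast",
    "epicardial cell",
    "perivascular cell",
    "smooth muscle cell",
    "macrophage",
    "monocyte",
    "T cell",
    "B cell",
)


def tpm(counts, lengths) -> np.ndarray:
    """Transcripts per million: TPM_i = 1e6 * (q_i/l_i) / sum_j(q_j/l_j).

    ``counts`` may be a vector (one sample) or a genes x samples matrix;
    ``lengths`` is per-gene transcript length in bp. Every column sums to
    1e6. Genes with zero length must have zero counts.
    """
    q = np.asarray(counts, dtype=float)
    l = np.asarray(lengths, dtype=float)
    one_d = q.ndim == 1
    if one_d:
        q = q[:, None]
    if l.shape[0] != q.shape[0]:
        raise ValueError("lengths must align with count rows")
    if np.any((l <= 0) & (q.sum(axis=1) > 0)):
        raise ValueError("genes with counts require positive lengths")
    safe_l = np.where(l > 0, l, 1.0)
    rate = q / safe_l[:, None]
    totals = rate.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("empty library: a sample has zero total counts")
    out = rate / totals * 1e6
    return out[:, 0] if one_d else out


@dataclass
class ExpressionTable:
    """Gene-level counts with transcript lengths and derived TPM."""

    counts: pd.DataFrame  # genes x samples
    lengths: pd.Series  # per gene, bp

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("every gene needs a transcript length")

    @property
    def tpm(self) -> pd.DataFrame:
        return pd.DataFrame(
            tpm(self.counts.to_numpy(), self.lengths.to_numpy()),
            index=self.counts.index,
            columns=self.counts.columns,
        )


@dataclass
class DEResult:
    """Per-gene differential expression table with columns gene, log2_fc,
    fold_change, p_value, fdr, significant."""

    table: pd.DataFrame
    dispersion: float
    size_factors: pd.Series

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "gene"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """DESeq-style size factors; falls back to total-count ratios when no
    gene is expressed in every sample."""
    logc = np.log(counts, where=counts > 0, out=np.full_like(counts, np.nan, dtype=float))
    all_pos = ~np.isnan(logc).any(axis=1)
    if all_pos.sum() == 0:
        totals = counts.sum(axis=0).astype(float)
        return totals / np.exp(np.mean(np.log(totals)))
    logmeans = logc[all_pos].mean(axis=1)
    sf = np.exp(np.median(logc[all_pos] - logmeans[:, None], axis=0))
    return sf


def differential_expression(
    counts: pd.DataFrame,
    design: Sequence[str],
    fc_threshold: float = 1.5,
    alpha: float = 0.1,
    criterion: str = "fdr",
    pseudocount: float = 0.5,
) -> DEResult:
    """Injured-vs-control differential test on a genes x samples count table.

    ``design`` labels each column "injured" or "control". The significance
    flag implements the rule used to select genes for the single-cell step:
    fold change > ``fc_threshold`` and FDR < ``alpha`` (defaults 1.5 / 0.1).
    """
    design = np.asarray(design)
    if len(design) != counts.shape[1]:
        raise ValueError("design must label every sample column")
    labels = set(design)
    if len(labels) < 2:
        raise ValueError("degenerate design: need two conditions")
    if labels - {"injured", "control"}:
        raise ValueError("design labels must be 'injured' or 'control'")

    mat = counts.to_numpy(dtype=float)
    if np.any(mat.sum(axis=0) == 0):
        raise ValueError("empty library: a sample has zero total counts")
    sf = _median_of_ratios(mat)
    norm = mat / sf
    mean_inj = norm[:, design == "injured"].mean(axis=1)
    mean_ctl = norm[:, design == "control"].mean(axis=1)
    fc = (mean_inj + pseudocount) / (mean_ctl + pseudocount)
    log2fc = np.log2(fc)

    dispersion = _stats.estimate_common_dispersion(norm, design)
    pvals = _stats.nb_two_group_pvalues(
        mat.astype(int), design, sf, dispersion, "injured"
    )
    fdr = _stats.bh_adjust(pvals)
    metric = fdr if criterion == "fdr" else pvals
    significant = (fc > fc_threshold) & (metric < alpha)

    table = pd.DataFrame(
        {
            "gene": counts.index,
            "log2_fc": log2fc,
            "fold_change": fc,
            "p_value": pvals,
            "fdr": fdr,
            "significant": significant,
        }
    )
    return DEResult(table, dispersion, pd.Series(sf, index=counts.columns))


@dataclass
class CellTypeAssignment:
    """Per-gene assigned cell type plus the per-type fold-change matrix the
    argmax was taken over."""

    assigned: pd.Series  # gene -> cell type
    fold_changes: pd.DataFrame  # genes x cell types


def assign_cell_types(
    sc_counts: pd.DataFrame,
    cell_meta: pd.DataFrame,
    gene_set: Sequence[str],
    pseudocount: float = 0.01,
    use_abs: bool = False,
    type_order: Optional[Sequence[str]] = None,
) -> CellTypeAssignment:
    """Assign each induced gene to the cell type with the largest change.

    ``sc_counts`` is genes x cells (raw counts); ``cell_meta`` is indexed by
    cell id with columns ``cell_type`` and ``condition`` ("injured" /
    "uninjured"). Per cell, counts are normalized as log1p(1e4 * count /
    cell_total); per gene per type the fold change of the mean normalized
    value (injured vs uninjured, pseudocount-guarded) is computed, and the
    gene goes to the argmax type. With ``use_abs`` the magnitude of change
    in either direction wins. Ties break by a fixed type order (the
    canonical cardiac list, then alphabetically). Types observed in only one
    condition are excluded with a warning.
    """
    cells = sc_counts.columns
    meta = cell_meta.loc[cells]
    totals = sc_counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(totals == 0):
        raise ValueError("a cell has zero total counts")
    normed = np.log1p(1e4 * sc_counts.to_numpy(dtype=float) / totals)

    types = list(dict.fromkeys(meta["cell_type"]))
    usable = []
    for t in types:
        conds = set(meta.loc[meta["cell_type"] == t, "condition"])
        if {INJURED, UNINJURED} <= conds:
            usable.append(t)
        else:
            warnings.warn(f"cell type {t!r} present in only one condition; excluded")
    if not usable:
        raise ValueError("no cell type observed in both conditions")

    if type_order is None:
        canon = [t for t in CANONICAL_CELL_TYPES if t in usable]
        rest = sorted(t for t in usable if t not in CANONICAL_CELL_TYPES)
        type_order = canon + rest
    else:
        type_order = [t for t in type_order if t in usable]

    genes = [g for g in gene_set if g in sc_counts.index]
    gidx = [sc_counts.index.get_loc(g) for g in genes]
    fcs = pd.DataFrame(index=genes, columns=type_order, dtype=float)
    cond = meta["condition"].to_numpy()
    ctype = meta["cell_type"].to_numpy()
    for t in type_order:
        inj = (ctype == t) & (cond == INJURED)
        uni = (ctype == t) & (cond == UNINJURED)
        mi = normed[np.ix_(gidx, np.flatnonzero(inj))].mean(axis=1)
        mu = normed[np.ix_(gidx, np.flatnonzero(uni))].mean(axis=1)
        fcs[t] = (mi + pseudocount) / (mu + pseudocount)

    score = fcs.to_numpy()
    if use_abs:
        score = np.maximum(score, 1.0 / score)
    # first occurrence in the fixed type order wins on ties
    assigned = pd.Series(
        [type_order[int(np.argmax(row))] for row in score], index=genes, name="cell_type"
    )
    return CellTypeAssignment(assigned, fcs)
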