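"""Region-level ChIP signal quantification and differential-enhancer calling.

An injury-responsive enhancer (IRE) is a distal enhancer whose H3K27ac
signal increases significantly after injury. The differential stage works
from a :class:`RegionCountTable` (regions x samples) and calls each region
IRE / non-IRE / excluded:

* IRE: fold change (injured vs control, pseudocounted normalized-count
  means) >= the
  threshold (default 1.5) and FDR (or p-value) below alpha;
* non-IRE: active in both conditions (mean CPM above a floor) with no
  significant increase;
* excluded: everything else (inactive regions, and promoter-proximal peaks
  once :func:`define_ires` applies the ±2 kb TSS exclusion).

Also here: deepTools-style signal matrices / metagene profiles around
anchors, k-means enhancer-state classification (poised / primed / active
from H3K27ac + H3K27me3), and 1 kb conservation window means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import _stats
from .intervals import GeneModel, GenomicInterval, exclude_promoter_proximal
from .tracks import CoverageTrack

__all__ = [
    "RegionCountTable",
    "DifferentialResult",
    "SignalMatrix",
    "region_counts",
    "build_count_table",
    "call_differential_regions",
    "define_ires",
    "signal_matrix",
    "classify_enhancer_states",
    "conservation_window_mean",
]

INJURED = "injured"
CONTROL = "control"


@dataclass
class RegionCountTable:
    """Integer read counts per region per sample.

    ``sample_meta`` is indexed by sample id with columns ``condition``
    ("injured"/"control"), ``replicate`` and ``library_size``.
    """

    regions: list[GenomicInterval]
    counts: np.ndarray
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.regions), len(self.sample_meta)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.regions)} regions x {len(self.sample_meta)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        for col in ("condition", "library_size"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta missing column {col!r}")
        colsums = self.counts.sum(axis=0)
        if (np.asarray(self.sample_meta["library_size"]) < colsums).any():
            raise ValueError("library_size must be >= column sum of counts")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.counts,
            index=[iv.name or f"region_{i}" for i, iv in enumerate(self.regions)],
            columns=self.sample_meta.index,
        )
        df.to_csv(path, sep="\t")


@dataclass
class DifferentialResult:
    """Per-region differential outcome; ``table`` has one row per region with
    columns region, log2_fc, fold_change, p_value, fdr, call."""

    table: pd.DataFrame
    fc_threshold: float
    alpha: float
    criterion: str
    dispersion: float

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def region_counts(
    track: CoverageTrack, regions: Sequence[GenomicInterval]
) -> np.ndarray:
    """Sum of per-base coverage within each region (regions beyond chromosome
    bounds are clipped with a warning)."""
    sizes = track.chrom_sizes()
    out = np.empty(len(regions))
    clipped = 0
    for i, iv in enumerate(regions):
        n = sizes.get(iv.chrom, 0)
        if iv.start < 0 or iv.end > n:
            clipped += 1
        vals = track.values(iv, pad=0.0)
        out[i] = float(np.nansum(vals))
    if clipped:
        warnings.warn(f"{clipped} region(s) extended beyond chromosome bounds; clipped")
    return out


def build_count_table(
    tracks: Mapping[str, CoverageTrack],
    regions: Sequence[GenomicInterval],
    sample_meta: pd.DataFrame,
) -> RegionCountTable:
    """Assemble a :class:`RegionCountTable` from one coverage track per sample
    (tracks keyed like ``sample_meta``'s index)."""
    counts = np.column_stack(
        [np.rint(region_counts(tracks[s], regions)) for s in sample_meta.index]
    ).astype(int)
    return RegionCountTable(list(regions), counts, sample_meta)


def call_differential_regions(
    table: RegionCountTable,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    criterion: str = "fdr",
    pseudocount: float = 0.5,
    activity_floor_cpm: float = 1.0,
) -> DifferentialResult:
    """Call injury-responsive regions from replicated injured/control counts.

    Fold change is computed on pseudocounted library-size-normalized means;
    significance comes
    from the conditional exact NB test with a common method-of-moments
    dispersion (see :mod:`irekit._stats`) and BH correction. ``criterion``
    selects whether ``alpha`` applies to the FDR (mouse-style rule,
    FDR < 0.05) or the raw p-value (zebrafish-style rule, p < 0.01).
    """
    if criterion not in ("fdr", "pvalue"):
        raise ValueError("criterion must be 'fdr' or 'pvalue'")
    counts = table.counts
    meta = table.sample_meta
    libsizes = np.asarray(meta["library_size"], dtype=float)
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("empty library: a sample has zero total counts")
    conds = np.asarray(meta["condition"])
    for c in (INJURED, CONTROL):
        if not (conds == c).any():
            raise ValueError(f"need at least one {c!r} sample")

    # normalized counts are invariant to a global rescale of library sizes,
    # so fold changes (and calls) do not depend on the library-size unit
    norm = counts / libsizes * libsizes.mean()
    mean_inj = norm[:, conds == INJURED].mean(axis=1)
    mean_ctl = norm[:, conds == CONTROL].mean(axis=1)
    fc = (mean_inj + pseudocount) / (mean_ctl + pseudocount)
    log2fc = np.log2(fc)

    cpm = counts / libsizes * 1e6
    cpm_inj = cpm[:, conds == INJURED].mean(axis=1)
    cpm_ctl = cpm[:, conds == CONTROL].mean(axis=1)

    dispersion = _stats.estimate_common_dispersion(norm, conds)
    pvals = _stats.nb_two_group_pvalues(counts, conds, libsizes, dispersion, INJURED)
    fdr = _stats.bh_adjust(pvals)

    metric = fdr if criterion == "fdr" else pvals
    up = (fc >= fc_threshold) & (metric < alpha)
    active_both = (cpm_inj >= activity_floor_cpm) & (cpm_ctl >= activity_floor_cpm)
    call = np.where(up, "IRE", np.where(active_both, "non-IRE", "excluded"))

    out = pd.DataFrame(
        {
            "region": [
                iv.name or f"region_{i}" for i, iv in enumerate(table.regions)
            ],
            "log2_fc": log2fc,
            "fold_change": fc,
            "p_value": pvals,
            "fdr": fdr,
            "call": call,
        }
    )
    return DifferentialResult(out, fc_threshold, alpha, criterion, dispersion)


def define_ires(
    peaks: Sequence[GenomicInterval],
    diff: DifferentialResult,
    genes: Sequence[GeneModel],
    flank: int = 2000,
) -> pd.Series:
    """Final IRE / non-IRE / excluded labels after promoter exclusion.

    Up-called peaks whose midpoint lies within ±``flank`` of any TSS are
    moved to "excluded" (IREs must be distal); other calls pass through.
    Returns a Series aligned with ``peaks``.
    """
    if len(peaks) != len(diff.table):
        raise ValueError("diff must be computed on the same peaks")
    final = []
    for peak, call in zip(peaks, diff.table["call"]):
        if call == "IRE" and not exclude_promoter_proximal([peak], genes, flank=flank):
            final.append("excluded")
        else:
            final.append(call)
    return pd.Series(final, name="call")


@dataclass
class SignalMatrix:
    """Binned signal around anchors: rows = anchors, columns = bins spanning
    [-flank, +flank) at ``bin_width`` resolution."""

    values: np.ndarray
    anchor: str
    flank: int
    bin_width: int
    row_names: Optional[list[str]] = None

    @property
    def profile(self) -> np.ndarray:
        """Column-mean metagene profile."""
        return np.nanmean(self.values, axis=0)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.row_names).to_csv(
            path, sep="\t", header=False
        )


def signal_matrix(
    track: CoverageTrack,
    anchors: Sequence[Union[GenomicInterval, GeneModel]],
    flank: int = 5000,
    bin_width: int = 100,
) -> SignalMatrix:
    """deepTools computeMatrix-style binned signal around anchor points.

    Interval anchors use their midpoint; gene anchors use the TSS and are
    strand-flipped so that the profile reads 5'->3'. Bases beyond chromosome
    ends contribute zeros (with a warning).
    """
    if flank % bin_width != 0:
        raise ValueError("flank must be divisible by bin_width")
    nbins = 2 * flank // bin_width
    sizes = track.chrom_sizes()
    rows = np.zeros((len(anchors), nbins))
    names = []
    warned = 0
    for i, a in enumerate(anchors):
        if isinstance(a, GeneModel):
            center, chrom, strand, name = a.tss, a.chrom, a.strand, a.gene_id
        else:
            center, chrom, strand, name = a.midpoint, a.chrom, a.strand, a.name
        names.append(name or f"anchor_{i}")
        start, end = center - flank, center + flank
        if start < 0 or end > sizes.get(chrom, 0):
            warned += 1
        vals = track.values_range(chrom, start, end, pad=0.0)
        row = np.nan_to_num(vals).reshape(nbins, bin_width).mean(axis=1)
        if strand == "-":
            row = row[::-1]
        rows[i] = row
    if warned:
        warnings.warn(f"{warned} anchor window(s) off chromosome; zero-padded")
    anchor_kind = "TSS" if anchors and isinstance(anchors[0], GeneModel) else "center"
    return SignalMatrix(rows, anchor_kind, flank, bin_width, names)


STATE_POISED = "poised"
STATE_PRIMED = "primed"
STATE_ACTIVE = "active"


def classify_enhancer_states(
    ac_matrix: SignalMatrix,
    me3_matrix: SignalMatrix,
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
) -> list[str]:
    """k-means (k=3) on concatenated H3K27ac/H3K27me3 row vectors, with
    clusters named by their mean signals: highest mean H3K27me3 -> poised;
    of the remaining two, higher mean H3K27ac -> active, the other primed.
    """
    ac, me3 = ac_matrix.values, me3_matrix.values
    if ac.shape[0] != me3.shape[0]:
        raise ValueError("matrices must be row-aligned (same enhancers)")
    n = ac.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of enhancers ({n})")
    X = np.hstack([ac, me3])
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    if k != 3:
        return [f"cluster_{c}" for c in labels]
    me3_means = np.array([me3[labels == c].mean() for c in range(3)])
    ac_means = np.array([ac[labels == c].mean() for c in range(3)])
    poised = int(np.argmax(me3_means))
    rest = [c for c in range(3) if c != poised]
    active = rest[int(np.argmax(ac_means[rest]))]
    primed = next(c for c in rest if c != active)
    name = {poised: STATE_POISED, active: STATE_ACTIVE, primed: STATE_PRIMED}
    return [name[c] for c in labels]


def conservation_window_mean(
    score_track: CoverageTrack,
    regions: Sequence[GenomicInterval],
    window: int = 1000,
) -> np.ndarray:
    """Mean per-base score in a ``window`` bp span centred on each region
    midpoint. Missing (NaN) bases are excluded from the mean; a fully missing
    window yields NaN (undefined, not zero)."""
    if window % 2 != 0:
        raise ValueError("window must be even")
    half = window // 2
    out = np.empty(len(regions))
    for i, iv in enumerate(regions):
        mid = iv.midpoint
        vals = score_track.values_range(iv.chrom, mid - half, mid + half)
        defined = vals[~np.isnan(vals)]
        out[i] = defined.mean() if defined.size else np.nan
    return out
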