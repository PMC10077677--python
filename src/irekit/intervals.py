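"""Genomic interval model and gene-linking operations.

Coordinates are 0-based, half-open (BED convention) throughout the package.
GTF input (1-based, inclusive) is converted on read; see :mod:`irekit.io`.

The operations here implement the region bookkeeping used by every later
stage of the injury-responsive-enhancer (IRE) analysis: nearest-gene
assignment of enhancers, the 100 kb proximity rule for enhancer-gene
linking, promoter exclusion (±2 kb around a TSS), and overlap queries
against annotation sets such as candidate cis-regulatory elements.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "AnnotationSet",
    "nearest_feature",
    "features_within",
    "exclude_promoter_proximal",
    "intersect_any",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored half-open span [start, end).

    ``strand`` is '+', '-' or '.' (unspecified).
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.chrom, self.start + offset, self.end + offset, self.name, self.strand
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS (one TSS per gene; no isoform awareness).

    ``ortholog_id`` optionally names the gene's counterpart in the other
    species, as resolved from an ortholog table.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    ortholog_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")


@dataclass
class AnnotationSet:
    """A labelled collection of intervals kept sorted by (chrom, start).

    Overlapping annotations are allowed; used e.g. for cCRE-ELS elements or
    TF ChIP peak sets.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    label: str = ""
    _by_chrom: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start))
        self._index()

    def _index(self) -> None:
        by_chrom: dict[str, tuple[list[int], list[GenomicInterval]]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, ([], []))
            starts, ivs = by_chrom[iv.chrom]
            starts.append(iv.start)
            ivs.append(iv)
        self._by_chrom = by_chrom

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def overlapping(self, query: GenomicInterval, min_overlap: int = 1) -> list[GenomicInterval]:
        """All annotations sharing >= min_overlap bases with ``query``."""
        if min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self._by_chrom is None:
            self._index()
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return []
        starts, ivs = entry
        # annotations are start-sorted; anything starting at/after query.end
        # cannot overlap. Earlier annotations may still reach into the query,
        # so scan left from the cut point.
        hi = bisect_left(starts, query.end)
        out = []
        for iv in ivs[:hi]:
            if iv.overlap(query) >= min_overlap:
                out.append(iv)
        return out


class NoFeaturesError(ValueError):
    pass


def nearest_feature(
    query: GenomicInterval, features: Sequence[GeneModel]
) -> tuple[Optional[GeneModel], Optional[int]]:
    """Gene whose TSS is closest to the query midpoint, with signed distance.

    Distance is ``tss - midpoint`` (negative = TSS upstream of midpoint in
    coordinate terms); 0 when the TSS lies inside the query. Ties are broken
    by smaller TSS coordinate, then lexicographic gene_id. Returns
    ``(None, None)`` when no feature shares the query's chromosome (the
    region is flagged unlinked rather than silently dropped).
    """
    if not features:
        raise NoFeaturesError("no features")
    mid = query.midpoint
    best: Optional[GeneModel] = None
    best_key: Optional[tuple] = None
    for g in features:
        if g.chrom != query.chrom:
            continue
        key = (abs(g.tss - mid), g.tss, g.gene_id)
        if best_key is None or key < best_key:
            best, best_key = g, key
    if best is None:
        return None, None
    if query.start <= best.tss < query.end:
        return best, 0
    return best, best.tss - mid


def features_within(
    query: GenomicInterval, features: Iterable[GeneModel], window: int
) -> list[GeneModel]:
    """Genes whose TSS lies within +-window bp of the query midpoint.

    The bound is closed: a TSS exactly ``window`` away is included.
    """
    if window < 0:
        raise ValueError("window must be positive")
    mid = query.midpoint
    return [
        g
        for g in features
        if g.chrom == query.chrom and abs(g.tss - mid) <= window
    ]


def exclude_promoter_proximal(
    peaks: Sequence[GenomicInterval],
    genes: Iterable[GeneModel],
    flank: int = 2000,
) -> list[GenomicInterval]:
    """Drop peaks whose midpoint falls in [tss - flank, tss + flank] of any gene.

    Mirrors the promoter-depletion rule used when defining distal enhancers
    (default ±2 kb around a TSS, assessed at the peak midpoint). Input order
    is preserved; with no genes, all peaks are kept.
    """
    tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    for v in tss_by_chrom.values():
        v.sort()
    kept = []
    for p in peaks:
        tsss = tss_by_chrom.get(p.chrom)
        if not tsss:
            kept.append(p)
            continue
        mid = p.midpoint
        i = bisect_right(tsss, mid)
        near = min(
            (abs(mid - tsss[j]) for j in (i - 1, i) if 0 <= j < len(tsss)),
        )
        if near > flank:
            kept.append(p)
    return kept


def intersect_any(
    queries: Sequence[GenomicInterval],
    annotations: AnnotationSet,
    min_overlap: int = 1,
) -> list[bool]:
    """Per query: does it overlap >= min_overlap bases of any annotation?"""
    return [bool(annotations.overlapping(q, min_overlap)) for q in queries]
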