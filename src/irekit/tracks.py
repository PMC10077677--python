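"""Per-base signal tracks (coverage or conservation scores).

A :class:`CoverageTrack` holds one float array per chromosome. Missing data
(conservation tracks) is represented as NaN. bedGraph round-trips are
supported; bigWig files can be read when pyBigWig is installed.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = ["CoverageTrack"]


class CoverageTrack:
    def __init__(self, arrays: Mapping[str, np.ndarray]):
        self._arrays = {c: np.asarray(a, dtype=float) for c, a in arrays.items()}

    @classmethod
    def zeros(cls, chrom_sizes: Mapping[str, int], fill: float = 0.0) -> "CoverageTrack":
        return cls({c: np.full(n, fill, dtype=float) for c, n in chrom_sizes.items()})

    @classmethod
    def from_bedgraph(cls, path, chrom_sizes: Mapping[str, int], missing=np.nan) -> "CoverageTrack":
        """Load a bedGraph (chrom, start, end, value). Bases not covered by
        any record take ``missing`` (NaN by default)."""
        track = cls({c: np.full(n, missing, dtype=float) for c, n in chrom_sizes.items()})
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        for row in df.itertuples(index=False):
            arr = track._arrays.get(row.chrom)
            if arr is None:
                continue
            arr[max(0, int(row.start)) : min(len(arr), int(row.end))] = float(row.value)
        return track

    @classmethod
    def from_bigwig(cls, path) -> "CoverageTrack":
        import pyBigWig  # optional dependency

        bw = pyBigWig.open(str(path))
        try:
            arrays = {
                c: np.array(bw.values(c, 0, n), dtype=float)
                for c, n in bw.chroms().items()
            }
        finally:
            bw.close()
        return cls(arrays)

    def to_bedgraph(self, path) -> None:
        """Write runs of equal defined values; NaN bases are omitted."""
        with open(path, "w") as fh:
            for chrom in self._arrays:
                arr = self._arrays[chrom]
                if arr.size == 0:
                    continue
                # run-length encode
                change = np.nonzero(arr[1:] != arr[:-1])[0] + 1
                # NaN != NaN, so NaN runs fragment; handle via isnan mask
                bounds = np.concatenate([[0], change, [arr.size]])
                prev_end = 0
                for b0, b1 in zip(bounds[:-1], bounds[1:]):
                    v = arr[b0]
                    if np.isnan(v):
                        continue
                    # merge adjacent equal-value runs that NaN splitting produced
                    fh.write(f"{chrom}\t{b0}\t{b1}\t{v:g}\n")
                    prev_end = b1

    def chrom_sizes(self) -> dict[str, int]:
        return {c: a.size for c, a in self._arrays.items()}

    def array(self, chrom: str) -> np.ndarray:
        return self._arrays[chrom]

    def values(self, interval: GenomicInterval, pad: float = np.nan) -> np.ndarray:
        """Per-base values over the interval; out-of-chromosome bases padded."""
        return self.values_range(interval.chrom, interval.start, interval.end, pad)

    def values_range(
        self, chrom: str, start: int, end: int, pad: float = np.nan
    ) -> np.ndarray:
        """Like :meth:`values` but on raw coordinates, which may run past
        either chromosome end (padded)."""
        arr = self._arrays.get(chrom)
        n = end - start
        out = np.full(n, pad)
        if arr is None:
            return out
        lo, hi = max(0, start), min(arr.size, end)
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def add(self, interval: GenomicInterval, value: float) -> None:
        arr = self._arrays[interval.chrom]
        lo, hi = max(0, interval.start), min(arr.size, interval.end)
        if hi > lo:
            arr[lo:hi] += value
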