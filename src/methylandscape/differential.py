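"""Differential-bin calling by fixed delta thresholds, and set overlaps.

No statistical test is involved: a bin is hypermethylated when its level
rises by at least the threshold (in percentage points, inclusive) between
the two genotypes, hypomethylated when it falls by at least as much.
Conventional thresholds: 20 points for CG bins, 10 for CA bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .binning import BinTrack

BinKey = tuple[str, int]


class GridMismatchError(ValueError):
    """The two bin tracks are not defined on the same bin grid."""


@dataclass
class MethylomeComparison:
    """Per-bin contrast between a control and a test methylome.

    ``frame`` holds one row per bin non-missing in both tracks: chrom,
    start, level_control, level_test, delta (test - control, percentage
    points).
    """

    frame: pd.DataFrame
    threshold_pct: float
    bin_size: int

    def _select(self, mask) -> set[BinKey]:
        sub = self.frame[mask]
        return set(zip(sub["chrom"], sub["start"]))

    @property
    def hyper(self) -> set[BinKey]:
        return self._select(self.frame["delta"] >= self.threshold_pct)

    @property
    def hypo(self) -> set[BinKey]:
        return self._select(self.frame["delta"] <= -self.threshold_pct)

    @property
    def n_paired(self) -> int:
        return len(self.frame)


def compare(bins_control: BinTrack, bins_test: BinTrack,
            threshold_pct: float = 20.0) -> MethylomeComparison:
    """Pair non-missing bins and call hyper/hypo sets at the threshold."""
    if threshold_pct <= 0:
        raise ValueError("threshold_pct must be > 0")
    if bins_control.bin_size != bins_test.bin_size:
        raise GridMismatchError(
            f"bin sizes differ: {bins_control.bin_size} vs {bins_test.bin_size}")
    if bins_control.keys() != bins_test.keys():
        raise GridMismatchError("bin grids differ between tracks")
    a = bins_control.covered[["chrom", "start", "level"]]
    b = bins_test.covered[["chrom", "start", "level"]]
    merged = a.merge(b, on=["chrom", "start"], suffixes=("_control", "_test"))
    merged = merged.rename(columns={"level_control": "level_control",
                                    "level_test": "level_test"})
    merged["delta"] = (merged["level_test"] - merged["level_control"]) * 100.0
    return MethylomeComparison(frame=merged.reset_index(drop=True),
                               threshold_pct=threshold_pct,
                               bin_size=bins_control.bin_size)


@dataclass(frozen=True)
class OverlapResult:
    n_intersection: int
    n_a_only: int
    n_b_only: int
    pct_of_a: float | None  # None when A is empty (undefined, not 0)
    pct_of_b: float | None


def overlap(set_a: Iterable[BinKey], set_b: Iterable[BinKey]) -> OverlapResult:
    """Venn counts and directional overlap percentages of two bin sets."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    return OverlapResult(
        n_intersection=inter,
        n_a_only=len(a - b),
        n_b_only=len(b - a),
        pct_of_a=100.0 * inter / len(a) if a else None,
        pct_of_b=100.0 * inter / len(b) if b else None,
    )


def stratify_by_delta(cmp: MethylomeComparison,
                      breaks: Sequence[float] = (20.0, 40.0, 60.0)
                      ) -> dict[str, set[BinKey]]:
    """Group bins into delta strata [b_i, b_{i+1}), last stratum [b_last, 100].

    When the first break equals the calling threshold the strata partition
    the hyper set exactly.
    """
    breaks = list(breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be strictly increasing")
    edges = breaks + [np.inf]
    out: dict[str, set[BinKey]] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        label = f"[{lo:g},{hi:g})" if np.isfinite(hi) else f"[{lo:g},100]"
        mask = (cmp.frame["delta"] >= lo) & (cmp.frame["delta"] < hi)
        sub = cmp.frame[mask]
        out[label] = set(zip(sub["chrom"], sub["start"]))
    return out
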