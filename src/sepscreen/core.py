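"""Rank-based separation statistic for two-group comparisons.

The separation statistic ``S`` quantifies how far apart the empirical
distributions of two groups of methylation beta values sit.  For an integer
percentile ``p`` it compares *opposite tails* of the two groups — the
``p``-th percentile of one group against the ``(100 - p)``-th percentile of
the other — and reports the largest ``p`` at which the tails are still
strictly ordered.  By construction ``S`` lies in ``[50, 100]``: 50 means the
two empirical distributions are indistinguishable through every cross-tail
comparison, 100 means the supports are disjoint (every value of one group
strictly exceeds every value of the other).

Two directional statistics are computed, one for each group sitting higher
(``M>F`` and ``F>M``); ``S`` is their maximum, and a selector count over the
full percentile range ``0..100`` assigns the direction label.  Percentiles
are nearest-rank order statistics (inverse empirical CDF), so every
percentile is an observed value and no interpolation is involved; ``S`` is
therefore invariant under strictly increasing transforms of the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Direction",
    "PercentileGrid",
    "TwoSampleData",
    "SeparationResult",
    "percentile",
    "directional_separation",
    "separation_statistic",
]

#: Floor of the directional search grid, and the value reported when no grid
#: point separates the groups (identical empirical distributions).
GRID_FLOOR = 50

#: Threshold on the selector count that assigns direction M>F.
SELECTOR_THRESHOLD = 50


class Direction(str, Enum):
    """Which group's methylation distribution sits higher at a site."""

    M_GT_F = "M>F"
    F_GT_M = "F>M"

    def flipped(self) -> "Direction":
        return Direction.F_GT_M if self is Direction.M_GT_F else Direction.M_GT_F


@dataclass(frozen=True)
class PercentileGrid:
    """Integer percentile grid scanned by the directional statistics.

    ``lo..hi`` (inclusive, percent scale) is the directional search range;
    the selector sum always runs over the full ``0..100`` range.
    """

    lo: int = GRID_FLOOR
    hi: int = 100

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi <= 100):
            raise ValueError(
                f"percentile grid must satisfy 0 <= lo <= hi <= 100, got [{self.lo}, {self.hi}]"
            )

    @property
    def points(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)


DEFAULT_GRID = PercentileGrid()


def _as_unit_fractions(values: Sequence[float], unit: str, what: str) -> np.ndarray:
    """Coerce a value sequence to a float array of fractions in [0, 1].

    ``unit`` is one of ``auto`` (any value > 1 implies a percent scale),
    ``fraction`` or ``percent``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{what}: group is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what}: values must be finite (missing values removed upstream)")
    if unit not in ("auto", "fraction", "percent"):
        raise ValueError(f"unknown unit {unit!r}; expected auto, fraction or percent")
    if unit == "percent" or (unit == "auto" and arr.max() > 1.0):
        arr = arr / 100.0
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(f"{what}: values outside [0, 1] after unit normalization")
    return arr


@dataclass
class TwoSampleData:
    """Methylation values of two mutually exclusive groups at one site.

    Values are accepted as fractions in [0, 1] or percentages in [0, 100]
    (``unit='auto'`` treats any value > 1 as evidence of the percent scale,
    applied to the pooled values of both groups) and stored as fractions.
    """

    values_m: Sequence[float]
    values_f: Sequence[float]
    unit: str = "auto"

    def __post_init__(self) -> None:
        pooled_unit = self.unit
        if pooled_unit == "auto":
            pooled = np.concatenate(
                [np.asarray(self.values_m, dtype=float).ravel(),
                 np.asarray(self.values_f, dtype=float).ravel()]
            )
            pooled_unit = "percent" if pooled.size and np.nanmax(pooled) > 1.0 else "fraction"
        self.values_m = _as_unit_fractions(self.values_m, pooled_unit, "group M")
        self.values_f = _as_unit_fractions(self.values_f, pooled_unit, "group F")

    @property
    def n_m(self) -> int:
        return self.values_m.size

    @property
    def n_f(self) -> int:
        return self.values_f.size

    def swapped(self) -> "TwoSampleData":
        """Return the same site with the two group labels exchanged."""
        return TwoSampleData(self.values_f.copy(), self.values_m.copy(), unit="fraction")


@dataclass(frozen=True)
class SeparationResult:
    """Separation statistic at one site, with direction and branch detail.

    ``selector_count`` is the number of percentiles ``p`` in ``0..100`` at
    which the ``p``-th percentile of group M lies strictly below the
    ``(100-p)``-th percentile of group F; counts of at most 50 label the
    direction M>F, larger counts F>M.
    """

    s: int
    direction: Direction
    s_m_gt_f: int
    s_f_gt_m: int
    selector_count: int

    def __post_init__(self) -> None:
        if not (GRID_FLOOR <= self.s <= 100):
            raise ValueError(f"separation statistic out of range [50, 100]: {self.s}")
        if self.s != max(self.s_m_gt_f, self.s_f_gt_m):
            raise ValueError("s must equal the larger directional statistic")


def _rank_indices(n: int) -> np.ndarray:
    """0-based nearest-rank index into a sorted sample of size ``n`` for each
    integer percentile 0..100: the minimum at p=0, else rank ceil(p*n/100)."""
    p = np.arange(101)
    idx = (p * n + 99) // 100 - 1  # ceil(p*n/100) - 1, integer-exact
    idx[0] = 0
    return idx


def percentile(values: Sequence[float], p: int) -> float:
    """Nearest-rank ``p``-th percentile (inverse empirical CDF) of ``values``.

    Returns the minimum for ``p = 0``; otherwise the element at 1-based rank
    ``ceil(p/100 * n)`` of the sorted values.  Always an observed value.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile of an empty sample is undefined")
    if not float(p).is_integer():
        raise ValueError(f"percentile index must be an integer percent, got {p!r}")
    p = int(p)
    if not 0 <= p <= 100:
        raise ValueError(f"percentile index must lie in [0, 100], got {p}")
    srt = np.sort(arr)
    if p == 0:
        return float(srt[0])
    return float(srt[math.ceil(p * arr.size / 100) - 1])


def _batch_separation(
    sorted_m: np.ndarray, sorted_f: np.ndarray, grid: PercentileGrid = DEFAULT_GRID
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized separation statistic over a batch of pre-sorted samples.

    ``sorted_m``/``sorted_f`` are 2-D arrays (batch × group size) with each
    row sorted ascending.  Returns ``(s, s_m_gt_f, s_f_gt_m, selector_count)``
    as integer arrays of length batch.  This is the single computational
    kernel behind the scalar API, the permutation engine and the screen.
    """
    ym = sorted_m[:, _rank_indices(sorted_m.shape[1])]  # (B, 101) order stats
    yf = sorted_f[:, _rank_indices(sorted_f.shape[1])]

    # Indicator at p = 0..100 of Y_M^(p) < Y_F^(100-p); its sum is the
    # direction selector, its upper-grid tail the F>M branch.
    cross_f = ym < yf[:, ::-1]
    selector_count = cross_f.sum(axis=1)

    lo, hi = grid.lo, grid.hi
    width = hi - lo + 1

    tail_f = cross_f[:, lo : hi + 1]
    s_f_gt_m = np.where(
        tail_f.any(axis=1),
        lo + (width - 1) - np.argmax(tail_f[:, ::-1], axis=1),
        lo,
    )

    # M>F branch: Y_M^(100-p) > Y_F^(p), i.e. the reversed-M order statistics
    # against F, scanned over the same grid.
    cross_m = ym[:, ::-1] > yf
    tail_m = cross_m[:, lo : hi + 1]
    s_m_gt_f = np.where(
        tail_m.any(axis=1),
        lo + (width - 1) - np.argmax(tail_m[:, ::-1], axis=1),
        lo,
    )

    s = np.maximum(s_m_gt_f, s_f_gt_m)
    return s, s_m_gt_f, s_f_gt_m, selector_count


def directional_separation(
    data: TwoSampleData, direction: Direction, grid: PercentileGrid = DEFAULT_GRID
) -> int:
    """Largest grid percentile at which the chosen cross-tail inequality holds.

    For ``F>M`` this is max{p : Y_M^(p) < Y_F^(100-p)}; for ``M>F`` it is
    max{p : Y_M^(100-p) > Y_F^(p)} — inequalities strict, ties do not count
    as separation.  Returns the grid floor when no grid point qualifies.
    """
    sm = np.sort(data.values_m)[None, :]
    sf = np.sort(data.values_f)[None, :]
    _, s_mgf, s_fgm, _ = _batch_separation(sm, sf, grid)
    return int(s_fgm[0] if direction is Direction.F_GT_M else s_mgf[0])


def separation_statistic(
    data: TwoSampleData, grid: PercentileGrid = DEFAULT_GRID
) -> SeparationResult:
    """Separation statistic ``S`` with direction for one two-group site.

    ``S`` is the maximum of the two directional statistics; the direction is
    assigned by the selector count (≤ 50 → M>F, otherwise F>M).  Degenerate
    groups (all values identical) are valid inputs and yield ``S = 50`` when
    the groups coincide.
    """
    sm = np.sort(data.values_m)[None, :]
    sf = np.sort(data.values_f)[None, :]
    s, s_mgf, s_fgm, count = _batch_separation(sm, sf, grid)
    direction = Direction.M_GT_F if count[0] <= SELECTOR_THRESHOLD else Direction.F_GT_M
    return SeparationResult(
        s=int(s[0]),
        direction=direction,
        s_m_gt_f=int(s_mgf[0]),
        s_f_gt_m=int(s_fgm[0]),
        selector_count=int(count[0]),
    )
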