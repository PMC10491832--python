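"""Permutation (randomization) inference for the separation statistic.

Under the sharp null hypothesis of no group difference the group labels are
exchangeable, so the null distribution of the separation statistic is the
distribution over relabelings of the observed values.  This module
approximates it by Monte-Carlo label shuffles (the screening default) and,
for small samples, computes it exactly by enumerating every distinct
assignment — the validation oracle for the Monte-Carlo path.

The Fisherian p-value is the proportion of null statistics at least as
large as the observed one (ties count as extreme).  Two conventions are
offered: ``add_one`` — (1 + #extreme) / (B + 1) — which treats the observed
labeling as one more draw from the null and guarantees p > 0 and exact
validity; and ``plain`` — #extreme / B — the literal proportion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .core import (
    DEFAULT_GRID,
    PercentileGrid,
    SeparationResult,
    TwoSampleData,
    _batch_separation,
    separation_statistic,
)

__all__ = [
    "PermutationConfig",
    "PermutationTestResult",
    "permute_labels",
    "permutation_test",
    "exact_enumeration_test",
]

#: Monte-Carlo draws used for the full-scale screen.
DEFAULT_N_PERM = 100_000

_CONVENTIONS = ("plain", "add_one")


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the Monte-Carlo permutation test.

    ``share_permutations`` reuses one sequence of label shuffles for every
    site of a screen (identical data then receive identical p-values);
    turning it off draws an independent sequence per site.
    """

    n_perm: int = DEFAULT_N_PERM
    seed: int = 0
    p_value_convention: str = "add_one"
    share_permutations: bool = True

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError(f"n_perm must be >= 1, got {self.n_perm}")
        if self.p_value_convention not in _CONVENTIONS:
            raise ValueError(
                f"p_value_convention must be one of {_CONVENTIONS}, got {self.p_value_convention!r}"
            )


@dataclass(frozen=True)
class PermutationTestResult:
    observed: SeparationResult
    p_value: float
    n_perm_used: int
    n_as_extreme: int


def _p_value(n_as_extreme: int, n_perm: int, convention: str) -> float:
    if convention == "plain":
        return n_as_extreme / n_perm
    return (1 + n_as_extreme) / (n_perm + 1)


def permute_labels(n_m: int, n_f: int, config: PermutationConfig) -> np.ndarray:
    """Uniform random reassignments of ``n_m + n_f`` samples into the groups.

    Returns a boolean matrix of shape ``(n_perm, n_m + n_f)`` where ``True``
    marks membership in group M; every row has exactly ``n_m`` True entries.
    Deterministic given ``config.seed``.
    """
    if n_m < 1 or n_f < 1:
        raise ValueError(f"both group sizes must be positive, got n_m={n_m}, n_f={n_f}")
    n = n_m + n_f
    rng = np.random.default_rng(config.seed)
    base = np.tile(np.arange(n) < n_m, (config.n_perm, 1))
    return rng.permuted(base, axis=1)


def _null_statistics(
    pooled: np.ndarray, masks: np.ndarray, n_m: int, n_f: int, grid: PercentileGrid
) -> np.ndarray:
    """Separation statistic for each relabeling in ``masks`` of ``pooled``."""
    # Rows of masks hold exactly n_m True entries, so pushing the other
    # group's values to +inf and sorting yields each group's sorted sample
    # in the leading columns — one sort per group for the whole batch.
    sm = np.sort(np.where(masks, pooled, np.inf), axis=1)[:, :n_m]
    sf = np.sort(np.where(masks, np.inf, pooled), axis=1)[:, :n_f]
    s, _, _, _ = _batch_separation(sm, sf, grid)
    return s


def permutation_test(
    data: TwoSampleData,
    config: PermutationConfig = PermutationConfig(),
    grid: PercentileGrid = DEFAULT_GRID,
) -> PermutationTestResult:
    """Monte-Carlo approximation of the randomization test of the sharp null.

    Computes the observed separation statistic on the actual labels, then
    the statistic under ``config.n_perm`` uniform label shuffles, and the
    Fisherian p-value with ties counted as extreme.
    """
    observed = separation_statistic(data, grid)
    pooled = np.concatenate([data.values_m, data.values_f])
    masks = permute_labels(data.n_m, data.n_f, config)
    s_null = _null_statistics(pooled, masks, data.n_m, data.n_f, grid)
    n_as_extreme = int(np.count_nonzero(s_null >= observed.s))
    return PermutationTestResult(
        observed=observed,
        p_value=_p_value(n_as_extreme, config.n_perm, config.p_value_convention),
        n_perm_used=config.n_perm,
        n_as_extreme=n_as_extreme,
    )


def exact_enumeration_test(
    data: TwoSampleData,
    max_combinations: int = 200_000,
    grid: PercentileGrid = DEFAULT_GRID,
) -> PermutationTestResult:
    """Exact randomization test over all distinct label assignments.

    Enumerates every way of assigning the pooled values to groups of the
    observed sizes (C(n_m + n_f, n_m) assignments, which includes the
    observed one) and reports the exact proportion of assignments with a
    statistic at least the observed — the ``plain`` convention, which is
    here exact rather than approximate.
    """
    n = data.n_m + data.n_f
    n_comb = math.comb(n, data.n_m)
    if n_comb > max_combinations:
        raise ValueError(
            f"{n_comb} label assignments exceed the enumeration budget of "
            f"{max_combinations}; use permutation_test for Monte-Carlo approximation"
        )
    observed = separation_statistic(data, grid)
    pooled = np.concatenate([data.values_m, data.values_f])
    masks = np.zeros((n_comb, n), dtype=bool)
    for row, members in enumerate(itertools.combinations(range(n), data.n_m)):
        masks[row, list(members)] = True
    s_null = _null_statistics(pooled, masks, data.n_m, data.n_f, grid)
    n_as_extreme = int(np.count_nonzero(s_null >= observed.s))
    return PermutationTestResult(
        observed=observed,
        p_value=n_as_extreme / n_comb,
        n_perm_used=n_comb,
        n_as_extreme=n_as_extreme,
    )
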