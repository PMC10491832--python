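"""Synthetic two-group methylation data with known ground truth.

Emulates the statistical structure the screen assumes: per-site
beta-distributed methylation fractions for two groups, with a configurable
fraction of sites carrying a planted group shift.  Defaults mirror the
balanced adult-cohort regime (385 samples per group); small unbalanced
designs (e.g. 15 vs 2) are equally valid.

Null sites draw both groups from one per-site Beta distribution whose mean
comes from a three-component mixture mimicking hypo-, hemi- and
hyper-methylated probes.  A planted effect shifts the elevated group's Beta
mean on the logit scale by ``delta`` while keeping the concentration
(alpha + beta) fixed, so values never leave [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .permutation import PermutationConfig
from .screening import (
    DEFAULT_P_MAX,
    DEFAULT_S_MIN,
    MethylationMatrix,
    SampleSheet,
    screen,
)

__all__ = [
    "SimulationSpec",
    "simulate_matrix",
    "estimate_type1_error",
    "estimate_power",
]

logger = logging.getLogger(__name__)

#: Null mixture over per-site Beta means: (weight, mean low, mean high) for
#: hypo- / hemi- / hyper-methylated probes, roughly the bimodal shape of
#: array beta values.
NULL_MEAN_MIXTURE = (
    (0.40, 0.05, 0.25),
    (0.20, 0.40, 0.60),
    (0.40, 0.75, 0.95),
)

#: Per-site Beta concentration (alpha + beta) range; larger is less noisy.
CONCENTRATION_RANGE = (20.0, 80.0)

#: Age range (years) of the simulated adult cohort, a bystander covariate.
AGE_RANGE = (48, 98)


class ErrorRateEstimate(NamedTuple):
    """A Monte-Carlo rate with its binomial standard error."""

    rate: float
    std_error: float
    n_sites: int


@dataclass(frozen=True)
class SimulationSpec:
    """Generative model of a two-group methylation matrix.

    ``delta`` is the logit-scale shift of the elevated group's Beta mean at
    differential sites; ``frac_m_gt_f`` is the fraction of those sites where
    group M is the elevated one.  ``null_alpha``/``null_beta``, when set,
    replace the mixture with one fixed Beta(alpha, beta) at every site.
    """

    n_m: int = 385
    n_f: int = 385
    n_sites: int = 1000
    frac_differential: float = 0.0
    delta: float = 2.0
    frac_m_gt_f: float = 0.5
    null_alpha: Optional[float] = None
    null_beta: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_m < 1 or self.n_f < 1:
            raise ValueError(f"group sizes must be positive, got n_m={self.n_m}, n_f={self.n_f}")
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be positive, got {self.n_sites}")
        for name in ("frac_differential", "frac_m_gt_f"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if (self.null_alpha is None) != (self.null_beta is None):
            raise ValueError("null_alpha and null_beta must be set together")
        if self.null_alpha is not None and (self.null_alpha <= 0 or self.null_beta <= 0):
            raise ValueError("Beta parameters must be positive")


def _logit(x: np.ndarray) -> np.ndarray:
    return np.log(x) - np.log1p(-x)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _site_means(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    weights = np.array([w for w, _, _ in NULL_MEAN_MIXTURE])
    comp = rng.choice(len(NULL_MEAN_MIXTURE), size=spec.n_sites, p=weights / weights.sum())
    lows = np.array([lo for _, lo, _ in NULL_MEAN_MIXTURE])[comp]
    highs = np.array([hi for _, _, hi in NULL_MEAN_MIXTURE])[comp]
    return rng.uniform(lows, highs)


def simulate_matrix(spec: SimulationSpec) -> tuple[MethylationMatrix, SampleSheet, pd.DataFrame]:
    """Draw a matrix, its sample sheet and the per-site truth table.

    The truth table has one row per probe with columns ``effect`` (one of
    ``null`` / ``M>F`` / ``F>M``) and ``delta`` (0 for null sites).
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_sites, n_m, n_f = spec.n_sites, spec.n_m, spec.n_f

    if spec.null_alpha is not None:
        mu = np.full(n_sites, spec.null_alpha / (spec.null_alpha + spec.null_beta))
        nu = np.full(n_sites, spec.null_alpha + spec.null_beta)
    else:
        mu = _site_means(spec, rng)
        nu = rng.uniform(*CONCENTRATION_RANGE, size=n_sites)

    n_diff = round(spec.frac_differential * n_sites)
    diff_sites = rng.choice(n_sites, size=n_diff, replace=False) if n_diff else np.array([], int)
    m_is_high = rng.random(n_diff) < spec.frac_m_gt_f

    mu_m = mu.copy()
    mu_f = mu.copy()
    shifted = _expit(_logit(mu[diff_sites]) + spec.delta)
    mu_m[diff_sites] = np.where(m_is_high, shifted, mu[diff_sites])
    mu_f[diff_sites] = np.where(m_is_high, mu[diff_sites], shifted)

    values_m = rng.beta(mu_m[:, None] * nu[:, None], (1 - mu_m[:, None]) * nu[:, None],
                        size=(n_sites, n_m))
    values_f = rng.beta(mu_f[:, None] * nu[:, None], (1 - mu_f[:, None]) * nu[:, None],
                        size=(n_sites, n_f))

    probe_ids = [f"cg{i:08d}" for i in range(1, n_sites + 1)]
    sample_ids = [f"M{i:04d}" for i in range(1, n_m + 1)] + [f"F{i:04d}" for i in range(1, n_f + 1)]
    matrix = MethylationMatrix(probe_ids, sample_ids,
                               np.concatenate([values_m, values_f], axis=1))

    ages = rng.integers(AGE_RANGE[0], AGE_RANGE[1] + 1, size=n_m + n_f)
    sheet = SampleSheet(
        sample_ids,
        ["M"] * n_m + ["F"] * n_f,
        covariates=pd.DataFrame({"age": ages}, index=sample_ids),
    )

    effect = np.full(n_sites, "null", dtype=object)
    effect[diff_sites[m_is_high]] = "M>F"
    effect[diff_sites[~m_is_high]] = "F>M"
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "effect": effect,
            "delta": np.where(effect == "null", 0.0, spec.delta),
        }
    )
    logger.info("simulated %d sites (%d differential) for %d + %d samples, seed %d",
                n_sites, n_diff, n_m, n_f, spec.seed)
    return matrix, sheet, truth


def estimate_type1_error(
    spec: SimulationSpec,
    perm_config: PermutationConfig,
    alpha: float = 0.05,
) -> ErrorRateEstimate:
    """Fraction of purely null sites with p ≤ ``alpha`` (the type-I rate).

    Requires a null spec (``frac_differential = 0``); the permutation test
    is level-valid by construction, so the rate should sit at or below
    ``alpha`` up to Monte-Carlo error.
    """
    if spec.frac_differential != 0:
        raise ValueError(
            f"type-I error needs a purely null spec; got frac_differential={spec.frac_differential}"
        )
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    matrix, sheet, _ = simulate_matrix(spec)
    records, _ = screen(matrix, sheet, perm_config)
    p = np.array([r.p_value for r in records])
    rate = float(np.mean(p <= alpha))
    se = math.sqrt(rate * (1 - rate) / p.size) if p.size else float("nan")
    return ErrorRateEstimate(rate, se, int(p.size))


def estimate_power(
    spec: SimulationSpec,
    perm_config: PermutationConfig,
    s_min: int = DEFAULT_S_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> ErrorRateEstimate:
    """Fraction of planted differential sites flagged by the joint rule."""
    if spec.frac_differential <= 0:
        raise ValueError("power estimation needs frac_differential > 0")
    matrix, sheet, truth = simulate_matrix(spec)
    records, _ = screen(matrix, sheet, perm_config, s_min=s_min, p_max=p_max)
    flagged = {r.probe_id for r in records if r.candidate}
    diff_ids = truth.loc[truth["effect"] != "null", "probe_id"]
    hits = diff_ids.isin(flagged)
    rate = float(hits.mean())
    se = math.sqrt(rate * (1 - rate) / len(hits)) if len(hits) else float("nan")
    return ErrorRateEstimate(rate, se, int(len(hits)))
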