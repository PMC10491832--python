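"""Epigenome-wide screen: separation statistic + permutation p-value per CpG.

Runs the two-group comparison at every probe of a methylation matrix,
flags candidates by the joint rule "high separation statistic and small
Fisherian p-value", and produces the results / volcano tables.  No
multiple-testing adjustment is applied: the screen takes a Fisherian
stance with fixed thresholds and emits raw p-values only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import DEFAULT_GRID, Direction, PercentileGrid, TwoSampleData, _batch_separation, separation_statistic
from .permutation import PermutationConfig, _null_statistics, _p_value, permute_labels

__all__ = [
    "MethylationMatrix",
    "SampleSheet",
    "ScreeningRecord",
    "SkippedProbe",
    "screen",
    "flag_candidates",
    "volcano_table",
    "results_frame",
    "volcano_plot",
]

logger = logging.getLogger(__name__)

#: Candidacy thresholds of the screen: separation statistic at least 80 and
#: Fisherian p-value below 1/100,000.
DEFAULT_S_MIN = 80
DEFAULT_P_MAX = 1e-5

#: Minimum non-missing values per group for a site to be tested.
MIN_GROUP_SIZE = 2

RESULT_COLUMNS = [
    "probe_id",
    "chromosome",
    "position",
    "gene",
    "n_m",
    "n_f",
    "separation_statistic",
    "direction",
    "p_value",
    "candidate",
    "skip_reason",
]


@dataclass
class MethylationMatrix:
    """Probe × sample beta-value matrix, values as fractions in [0, 1].

    Missing values are NaN.  Probe and sample identifiers are unique and
    keep their input order.
    """

    probe_ids: Sequence[str]
    sample_ids: Sequence[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = list(map(str, self.probe_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {name} identifiers: {dupes[:5]}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("beta values must lie in [0, 1] (fractions) after normalization")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.probe_ids, name="probe_id"),
                            columns=self.sample_ids)


@dataclass
class SampleSheet:
    """Assignment of samples to the two groups, plus optional covariates.

    Group labels are the canonical strings "M" and "F".  Covariates (age,
    batch, …) are carried for external inspection only; the screen itself
    never adjusts for them.
    """

    sample_ids: Sequence[str]
    group: Sequence[str]
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.group = list(self.group)
        if len(self.sample_ids) != len(self.group):
            raise ValueError("sample_ids and group must have equal length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers in sample sheet")
        bad = sorted({g for g in self.group if g not in ("M", "F")})
        if bad:
            raise ValueError(f"unknown group labels {bad}; expected 'M' or 'F'")
        if "M" not in self.group or "F" not in self.group:
            raise ValueError("both groups must be non-empty")

    @property
    def n_m(self) -> int:
        return self.group.count("M")

    @property
    def n_f(self) -> int:
        return self.group.count("F")

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.group))


@dataclass
class ScreeningRecord:
    """Per-probe result of the screen."""

    probe_id: str
    s: int
    direction: Direction
    p_value: float
    n_m: int
    n_f: int
    candidate: bool
    chromosome: str = ""
    position: str = ""
    gene: str = ""


@dataclass(frozen=True)
class SkippedProbe:
    probe_id: str
    reason: str


def _probe_masks(n_m: int, n_f: int, perm_config: PermutationConfig, probe_index: int) -> np.ndarray:
    """Label shuffles for one probe that could not use the shared set."""
    seed = np.random.SeedSequence([perm_config.seed, probe_index]).generate_state(1)[0]
    cfg = PermutationConfig(
        n_perm=perm_config.n_perm,
        seed=int(seed),
        p_value_convention=perm_config.p_value_convention,
        share_permutations=False,
    )
    return permute_labels(n_m, n_f, cfg)


def screen(
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    perm_config: PermutationConfig = PermutationConfig(),
    grid: PercentileGrid = DEFAULT_GRID,
    s_min: int = DEFAULT_S_MIN,
    p_max: float = DEFAULT_P_MAX,
    annotation: Optional[pd.DataFrame] = None,
) -> tuple[list[ScreeningRecord], list[SkippedProbe]]:
    """Test the sharp null of no group difference at every probe.

    Returns one :class:`ScreeningRecord` per tested probe and one
    :class:`SkippedProbe` per probe that could not be tested (fewer than
    two non-missing values in either group).  With
    ``perm_config.share_permutations`` (the default) a single sequence of
    label shuffles is reused across all complete-data probes; probes with
    missing values, whose pooled sample is smaller, get a deterministic
    per-probe sequence derived from the same seed.

    ``annotation``, if given, is indexed by probe id with columns
    chromosome / position / gene; unannotated probes carry empty fields.
    """
    sheet_groups = sheet.group_of()
    missing = [s for s in matrix.sample_ids if s not in sheet_groups]
    if len(missing) == len(matrix.sample_ids):
        raise ValueError("no overlap between matrix samples and sample sheet")
    if missing:
        raise ValueError(
            f"{len(missing)} matrix samples absent from the sample sheet "
            f"(first: {missing[:5]})"
        )
    groups = np.array([sheet_groups[s] for s in matrix.sample_ids])
    m_cols = np.nonzero(groups == "M")[0]
    f_cols = np.nonzero(groups == "F")[0]
    if m_cols.size == 0 or f_cols.size == 0:
        raise ValueError("both groups must be represented among the matrix samples")
    n_m_full, n_f_full = m_cols.size, f_cols.size

    shared_masks: Optional[np.ndarray] = None
    if perm_config.share_permutations:
        shared_masks = permute_labels(n_m_full, n_f_full, perm_config)

    ann = annotation if annotation is not None else pd.DataFrame()
    records: list[ScreeningRecord] = []
    skipped: list[SkippedProbe] = []
    n_missing_dropped = 0

    for i, probe in enumerate(matrix.probe_ids):
        row = matrix.values[i]
        vm = row[m_cols]
        vf = row[f_cols]
        vm = vm[np.isfinite(vm)]
        vf = vf[np.isfinite(vf)]
        dropped = (n_m_full - vm.size) + (n_f_full - vf.size)
        n_missing_dropped += dropped
        if vm.size < MIN_GROUP_SIZE or vf.size < MIN_GROUP_SIZE:
            which = "M" if vm.size < MIN_GROUP_SIZE else "F"
            skipped.append(SkippedProbe(probe, f"fewer than {MIN_GROUP_SIZE} non-missing values in group {which}"))
            continue

        data = TwoSampleData(vm, vf, unit="fraction")
        observed = separation_statistic(data, grid)
        pooled = np.concatenate([data.values_m, data.values_f])
        if shared_masks is not None and vm.size == n_m_full and vf.size == n_f_full:
            masks = shared_masks
        else:
            masks = _probe_masks(vm.size, vf.size, perm_config, i)
        s_null = _null_statistics(pooled, masks, vm.size, vf.size, grid)
        k = int(np.count_nonzero(s_null >= observed.s))
        p = _p_value(k, perm_config.n_perm, perm_config.p_value_convention)

        meta = {"chromosome": "", "position": "", "gene": ""}
        if probe in ann.index:
            arow = ann.loc[probe]
            for key in meta:
                if key in arow.index and pd.notna(arow[key]):
                    meta[key] = str(arow[key])
        records.append(
            ScreeningRecord(
                probe_id=probe,
                s=observed.s,
                direction=observed.direction,
                p_value=p,
                n_m=int(vm.size),
                n_f=int(vf.size),
                candidate=(observed.s >= s_min) and (p < p_max),
                **meta,
            )
        )

    n_flagged = sum(r.candidate for r in records)
    logger.info(
        "screened %d probes: %d tested, %d skipped, %d missing values dropped, "
        "%d candidates (S >= %d, p < %g)",
        matrix.n_probes, len(records), len(skipped), n_missing_dropped,
        n_flagged, s_min, p_max,
    )
    return records, skipped


def flag_candidates(
    records: Sequence[ScreeningRecord],
    s_min: int = DEFAULT_S_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> list[ScreeningRecord]:
    """Probes worth further scrutiny: S ≥ ``s_min`` and p < ``p_max``."""
    if not records:
        raise ValueError("no screening records to filter")
    kept = [r for r in records if r.s >= s_min and r.p_value < p_max]
    logger.info("flagged %d of %d records at S >= %d and p < %g",
                len(kept), len(records), s_min, p_max)
    return kept


def volcano_table(records: Sequence[ScreeningRecord]) -> pd.DataFrame:
    """One row per record with (s, p_value, direction) for volcano plotting.

    The direction column partitions rows into the two panels of the plot;
    p-values are carried through unmodified.
    """
    if not records:
        raise ValueError("no screening records to tabulate")
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "s": [r.s for r in records],
            "p_value": [r.p_value for r in records],
            "direction": [r.direction.value for r in records],
        }
    )


def results_frame(
    records: Sequence[ScreeningRecord],
    skipped: Sequence[SkippedProbe] = (),
) -> pd.DataFrame:
    """Full results table (tested and skipped probes) in the output schema."""
    rows = [
        {
            "probe_id": r.probe_id,
            "chromosome": r.chromosome,
            "position": r.position,
            "gene": r.gene,
            "n_m": r.n_m,
            "n_f": r.n_f,
            "separation_statistic": r.s,
            "direction": r.direction.value,
            "p_value": r.p_value,
            "candidate": int(r.candidate),
            "skip_reason": "",
        }
        for r in records
    ] + [
        {
            "probe_id": sk.probe_id,
            "chromosome": "", "position": "", "gene": "",
            "n_m": "", "n_f": "", "separation_statistic": "",
            "direction": "", "p_value": "", "candidate": "",
            "skip_reason": sk.reason,
        }
        for sk in skipped
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def volcano_plot(records: Sequence[ScreeningRecord], path: str) -> None:
    """Two-panel volcano plot (one panel per direction): S against p-value.

    The y axis shows -log10(p); sites with higher methylation in group M on
    the left panel, in group F on the right.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = volcano_table(records)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True, sharex=True)
    for ax, direction in zip(axes, (Direction.M_GT_F, Direction.F_GT_M)):
        sub = table[table["direction"] == direction.value]
        # plain-convention p-values can be exactly 0; clip for the log axis
        logp = -np.log10(np.maximum(sub["p_value"].to_numpy(float), 1e-12))
        ax.scatter(sub["s"], logp, s=8, alpha=0.6)
        ax.set_title(f"scenario {direction.value}")
        ax.set_xlabel("separation statistic")
    axes[0].set_ylabel("-log10 Fisherian p-value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
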