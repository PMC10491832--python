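"""Reading and writing the tabular formats of the screen.

Formats are deliberately plain: a delimited probe × sample matrix with a
header row of sample ids, a CSV sample sheet (sample_id, group[, covariates]),
a plain-text probe-exclusion list (one probe id per line, ``#`` comments),
a delimited annotation table (probe_id, chromosome, position, gene), and
the tab-separated results table of the screening module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .screening import (
    MethylationMatrix,
    SampleSheet,
    ScreeningRecord,
    SkippedProbe,
    results_frame,
)

__all__ = [
    "ProbeExclusionList",
    "read_matrix",
    "write_matrix",
    "read_sample_sheet",
    "read_exclusion_list",
    "read_annotation",
    "apply_probe_filter",
    "write_results",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_GROUP_ALIASES = {"m": "M", "male": "M", "f": "F", "female": "F"}


@dataclass(frozen=True)
class ProbeExclusionList:
    """Probe ids to drop before screening (e.g. non-specific array probes)."""

    probe_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.probe_ids)


def _read_delimited(path: PathLike, delimiter: Optional[str], index_col=0) -> pd.DataFrame:
    """Read a delimited table, sniffing TSV vs CSV from the header when no
    delimiter is given."""
    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=delimiter, index_col=index_col)


def read_matrix(
    path: PathLike,
    unit_hint: str = "auto",
    delimiter: Optional[str] = None,
) -> MethylationMatrix:
    """Read a probe × sample beta-value matrix and normalize to fractions.

    ``unit_hint='auto'`` treats any value > 1 as evidence of a percent
    scale; ``fraction`` / ``percent`` force the interpretation.  Missing
    cells are tolerated (empty or NA); a value outside [0, 100] raises an
    error naming the offending cell.
    """
    if unit_hint not in ("auto", "fraction", "percent"):
        raise ValueError(f"unit_hint must be auto, fraction or percent, got {unit_hint!r}")
    frame = _read_delimited(path, delimiter)
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe ids in {path}: {dupes[:5]}")
    if frame.columns.has_duplicates:
        dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dupes[:5]}")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric beta value in {path}: {exc}") from exc

    finite = np.isfinite(values)
    bad = finite & ((values < 0.0) | (values > 100.0))
    if bad.any():
        r, c = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"beta value {values[r, c]!r} outside [0, 100] at probe "
            f"{frame.index[r]!r}, sample {frame.columns[c]!r} in {path}"
        )
    max_seen = values[finite].max() if finite.any() else 0.0
    if unit_hint == "percent" or (unit_hint == "auto" and max_seen > 1.0):
        values = values / 100.0
    if finite.any() and values[finite].max() > 1.0:
        # only reachable with unit_hint='fraction' and percent-scale input
        r, c = map(int, np.argwhere(finite & (values > 1.0))[0])
        raise ValueError(
            f"beta value {frame.iat[r, c]!r} exceeds 1 at probe {frame.index[r]!r}, "
            f"sample {frame.columns[c]!r} but unit_hint='fraction'"
        )
    logger.info("read matrix %s: %d probes x %d samples", path, *values.shape)
    return MethylationMatrix(frame.index.tolist(), frame.columns.tolist(), values)


def write_matrix(matrix: MethylationMatrix, path: PathLike, delimiter: str = "\t") -> None:
    """Write the matrix as delimited text (fractions, full precision)."""
    matrix.to_frame().to_csv(path, sep=delimiter)


def read_sample_sheet(path: PathLike) -> SampleSheet:
    """Read a CSV sample sheet with at least ``sample_id`` and ``group``.

    Group labels are mapped case-insensitively from {M, male, F, female};
    any other label is rejected.  Remaining columns are kept as covariates.
    """
    frame = pd.read_csv(path)
    frame.columns = [c.strip().lower() for c in frame.columns]
    for col in ("sample_id", "group"):
        if col not in frame.columns:
            raise ValueError(f"sample sheet {path} lacks required column {col!r}")
    sample_ids = frame["sample_id"].astype(str).tolist()
    groups = []
    for sid, raw in zip(sample_ids, frame["group"]):
        key = str(raw).strip().lower()
        if key not in _GROUP_ALIASES:
            raise ValueError(f"sample {sid!r} has unmapped group label {raw!r} in {path}")
        groups.append(_GROUP_ALIASES[key])
    covars = frame.drop(columns=["sample_id", "group"])
    covariates = covars.set_axis(sample_ids) if not covars.empty else None
    sheet = SampleSheet(sample_ids, groups, covariates)
    logger.info("read sample sheet %s: %d M, %d F", path, sheet.n_m, sheet.n_f)
    return sheet


def read_exclusion_list(path: PathLike) -> ProbeExclusionList:
    """Read a plain-text probe list: one id per line, ``#`` starts a comment."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                ids.add(entry)
    return ProbeExclusionList(frozenset(ids))


def read_annotation(path: PathLike, delimiter: Optional[str] = None) -> pd.DataFrame:
    """Read a probe annotation table indexed by probe id.

    Expected columns: probe_id, chromosome, position, gene (extra columns
    are kept).  Probes without annotation simply stay unannotated in the
    results; they are never dropped.
    """
    frame = _read_delimited(path, delimiter, index_col=None)
    frame.columns = [c.strip().lower() for c in frame.columns]
    if "probe_id" not in frame.columns:
        raise ValueError(f"annotation table {path} lacks a probe_id column")
    return frame.set_index(frame["probe_id"].astype(str)).drop(columns=["probe_id"])


def apply_probe_filter(
    matrix: MethylationMatrix, exclusion: ProbeExclusionList
) -> MethylationMatrix:
    """Drop excluded probes from the matrix (idempotent).

    Listed probes absent from the matrix are ignored with a logged count.
    """
    present = set(matrix.probe_ids)
    removed = present & exclusion.probe_ids
    ignored = len(exclusion.probe_ids - present)
    keep = [i for i, p in enumerate(matrix.probe_ids) if p not in removed]
    logger.info("probe filter: removed %d probes, ignored %d unknown ids", len(removed), ignored)
    return MethylationMatrix(
        [matrix.probe_ids[i] for i in keep],
        matrix.sample_ids,
        matrix.values[keep, :],
    )


def write_results(
    records: Sequence[ScreeningRecord],
    path: PathLike,
    skipped: Sequence[SkippedProbe] = (),
) -> None:
    """Write the screening results as the canonical TSV."""
    results_frame(records, skipped).to_csv(path, sep="\t", index=False)
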