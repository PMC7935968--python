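"""Tabular input/output: pressure, OD and GC time series in, result tables out.

Input CSVs carry a header with columns ``time_h`` and ``value`` (plus an
optional ``vessel_id`` for multi-reactor files); times are in hours with '.'
as decimal separator.  Output tables are TSV with a fixed column order,
floats at 6 significant digits and deterministic row ordering, so identical
inputs always produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gas_model import VesselSpec

__all__ = [
    "PressureSeries",
    "ODSeries",
    "GCResult",
    "read_timeseries",
    "write_results",
]

logger = logging.getLogger(__name__)


@dataclass
class PressureSeries:
    """Timestamped gauge-pressure trace for one vessel (hours, bar)."""

    vessel_id: str
    times: np.ndarray
    pressures: np.ndarray
    vessel: VesselSpec | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.times.size != self.pressures.size:
            raise ValueError("times and pressures differ in length")
        if self.times.size < 2:
            raise ValueError("a pressure series needs at least 2 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"times of vessel {self.vessel_id!r} are not strictly increasing")
        if np.isnan(self.pressures).any():
            raise ValueError(f"vessel {self.vessel_id!r} has missing pressure values")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class ODSeries:
    """Optical-density (OD578) trace for one vessel."""

    vessel_id: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size != self.od.size:
            raise ValueError("times and od differ in length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"times of vessel {self.vessel_id!r} are not strictly increasing")
        if np.any(self.od < 0):
            raise ValueError(f"vessel {self.vessel_id!r} has negative OD values")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class GCResult:
    """End-point GC off-gas methane fraction for one vessel."""

    vessel_id: str
    y_ch4: float
    sampled_at: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.y_ch4 <= 1.0:
            raise ValueError(f"y_ch4={self.y_ch4} outside [0, 1]")


_KINDS = ("pressure", "od", "gc")


def _load_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    for col in ("time_h", "value"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "vessel_id" not in frame.columns:
        frame["vessel_id"] = "R1"
    return frame


def _dedupe(group: pd.DataFrame, vessel_id: str, path: Path) -> pd.DataFrame:
    group = group.sort_values("time_h", kind="mergesort")
    if group["time_h"].duplicated().any():
        n_dup = int(group["time_h"].duplicated().sum())
        logger.warning(
            "%s: vessel %s has %d duplicate timestamps; collapsing by mean",
            path, vessel_id, n_dup,
        )
        group = group.groupby("time_h", as_index=False)["value"].mean()
    return group


def read_timeseries(
    path: str | Path,
    kind: str,
    vessel: VesselSpec | None = None,
) -> list[PressureSeries] | list[ODSeries] | list[GCResult]:
    """Read a CSV time-series file into one series per vessel_id.

    Rows are sorted by time; duplicate timestamps are collapsed by mean
    with a logged warning.  ``kind`` selects the returned type: 'pressure'
    -> PressureSeries, 'od' -> ODSeries, 'gc' -> one GCResult per row.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {_KINDS}")
    path = Path(path)
    frame = _load_frame(path)
    out: list = []
    for vessel_id, group in frame.groupby("vessel_id", sort=True):
        vessel_id = str(vessel_id)
        if kind == "gc":
            for _, row in group.sort_values("time_h").iterrows():
                out.append(GCResult(vessel_id, float(row["value"]), float(row["time_h"])))
            continue
        group = _dedupe(group, vessel_id, path)
        times = group["time_h"].to_numpy(dtype=float)
        values = group["value"].to_numpy(dtype=float)
        if kind == "pressure":
            out.append(PressureSeries(vessel_id, times, values, vessel=vessel))
        else:
            out.append(ODSeries(vessel_id, times, values))
    return out


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool) or isinstance(value, np.bool_):
        return "true" if value else "false"
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def _sort_key(row) -> tuple:
    key = []
    for attr in ("vessel_id", "cycle", "strain_id", "seq_id"):
        if hasattr(row, attr):
            key.append(getattr(row, attr))
    return tuple(key)


def write_results(results: Sequence, path: str | Path) -> Path:
    """Write a homogeneous collection of result records as a TSV table.

    All records must be dataclass instances of the same type; the field
    order of the dataclass fixes the column order, floats are rendered at
    6 significant digits and rows are sorted by (vessel_id, cycle,
    strain/sequence id) so repeated writes are byte-identical.
    """
    results = list(results)
    if not results:
        raise ValueError("results collection is empty")
    first_type = type(results[0])
    if not dataclasses.is_dataclass(results[0]):
        raise TypeError(f"cannot serialize {first_type.__name__}: not a result record")
    if any(type(r) is not first_type for r in results):
        raise TypeError("mixed result kinds in one write_results call")
    fields = [f.name for f in dataclasses.fields(first_type) if not f.name.startswith("_")]
    rows = sorted(results, key=_sort_key)
    path = Path(path)
    lines = ["\t".join(fields)]
    for row in rows:
        lines.append("\t".join(_fmt(getattr(row, name)) for name in fields))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
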