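"""Trace container and tidy-CSV dataset I/O.

A :class:`RheometerTrace` is a tidy frame of time-resolved raw signals from
one protocol segment plus a metadata dictionary (phantom, protocol, segment
boundaries).  Datasets are written as one CSV per trace with a JSON sidecar
carrying the metadata, so everything stays plain text and round-trips
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = ["RheometerTrace", "TRACE_COLUMNS", "write_dataset", "read_dataset",
           "write_trace", "read_trace"]

TRACE_COLUMNS = ("time_s", "shear_strain", "shear_stress_pa",
                 "normal_force_n", "gap_mm")


@dataclass
class RheometerTrace:
    """Time-resolved raw signals from one protocol segment.

    ``data`` columns: ``time_s, shear_strain, shear_stress_pa,
    normal_force_n, gap_mm``; time must be strictly increasing and no value
    may be missing.  ``metadata`` identifies the phantom and protocol and may
    carry a ``segments`` list (start/stop sample indices, amplitude,
    frequency, axial strain per measurement plateau).
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"trace is missing column(s): {missing}")
        if self.data[list(TRACE_COLUMNS)].isna().any().any():
            raise ValidationError("trace contains missing values")
        t = self.data["time_s"].to_numpy()
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValidationError("time must be strictly increasing")

    # array views -----------------------------------------------------------
    @property
    def time(self) -> np.ndarray:
        return self.data["time_s"].to_numpy()

    @property
    def shear_strain(self) -> np.ndarray:
        return self.data["shear_strain"].to_numpy()

    @property
    def shear_stress(self) -> np.ndarray:
        return self.data["shear_stress_pa"].to_numpy()

    @property
    def normal_force(self) -> np.ndarray:
        return self.data["normal_force_n"].to_numpy()

    @property
    def gap(self) -> np.ndarray:
        return self.data["gap_mm"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def equals(self, other: "RheometerTrace") -> bool:
        return self.data.equals(other.data) and self.metadata == other.metadata


def _sidecar(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_trace(trace: RheometerTrace, csv_path) -> Path:
    """Write one trace as CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    trace.data.to_csv(csv_path, index=False, float_format="%.12g")
    with open(_sidecar(csv_path), "w", encoding="utf-8") as fh:
        json.dump(trace.metadata, fh, indent=1, sort_keys=True)
    return csv_path


def read_trace(csv_path) -> RheometerTrace:
    """Read one trace written by :func:`write_trace`.

    Raises :class:`~liverrheo.exceptions.FormatError` naming the first
    missing column if the CSV header does not conform to the schema.
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise FormatError(
                f"{csv_path.name}: required column {col!r} is missing"
            )
        df[col] = df[col].astype(float)
    meta = {}
    side = _sidecar(csv_path)
    if side.exists():
        with open(side, encoding="utf-8") as fh:
            meta = json.load(fh)
    return RheometerTrace(df, meta)


def write_dataset(traces, path) -> list[Path]:
    """Write a list of traces into a directory (trace_0000.csv, ...)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for i, trace in enumerate(traces):
        written.append(write_trace(trace, path / f"trace_{i:04d}.csv"))
    return written


def read_dataset(path) -> list[RheometerTrace]:
    """Read every trace CSV in a directory, in filename order."""
    path = Path(path)
    if path.is_file():
        return [read_trace(path)]
    files = sorted(p for p in path.glob("*.csv"))
    if not files:
        raise FormatError(f"no trace CSV files found under {path}")
    return [read_trace(p) for p in files]
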