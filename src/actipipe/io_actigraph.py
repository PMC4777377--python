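"""Count-series I/O in a plain, inspectable CSV dialect.

The dialect mirrors vendor count exports: a two-line header declaring the
recording start time and the epoch length, a column-name row, then one data
row per epoch::

    start_time,2014-01-06 00:00:00
    epoch_length,60
    timestamp,axis1,axis2,axis3,vm
    2014-01-06 00:00:00,0,0,0,0.00
    2014-01-06 00:01:00,3,4,0,5.00

Axis counts are non-negative integers; the vector magnitude (``vm``) column
is written with two decimals for convenience but is always recomputed
exactly from the three axes on read. Timestamps are naive local time — day
boundaries and the 5:00 AM scoring window are defined on the device clock.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "CountSeries",
    "CountsFormatError",
    "CountsValidationError",
    "read_counts_csv",
    "write_counts_csv",
]

#: epoch lengths (seconds) the pipeline operates on; all divide 60 so that
#: 60-s reintegration blocks align with clock minutes
VALID_EPOCHS = (1, 5, 10, 15, 30, 60)

TIME_FORMAT = "%Y-%m-%d %H:%M:%S"


class CountsFormatError(ValueError):
    """Malformed header or row structure in a counts CSV."""


class CountsValidationError(ValueError):
    """Structurally sound file with invalid values (negative / non-integer)."""


@dataclass
class CountSeries:
    """Time-stamped per-axis activity counts at a fixed epoch length.

    ``axis1`` is the vertical axis. ``vm`` is the per-epoch Euclidean norm of
    the three axes; it is stored for convenience and re-derivable at any time.
    """

    start_time: datetime
    epoch_length: int
    axis1: np.ndarray
    axis2: np.ndarray
    axis3: np.ndarray
    vm: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.epoch_length not in VALID_EPOCHS:
            raise CountsValidationError(
                f"epoch_length must be one of {VALID_EPOCHS}, got {self.epoch_length}"
            )
        self.axis1 = _as_count_array(self.axis1, "axis1")
        self.axis2 = _as_count_array(self.axis2, "axis2")
        self.axis3 = _as_count_array(self.axis3, "axis3")
        n = len(self.axis1)
        if not (len(self.axis2) == len(self.axis3) == n):
            raise CountsValidationError("axis arrays must have equal length")
        if self.vm is None:
            self.vm = compute_vm(self.axis1, self.axis2, self.axis3)
        else:
            self.vm = np.asarray(self.vm, dtype=np.float64)
            if len(self.vm) != n:
                raise CountsValidationError("vm length must match axis length")
            if not np.all(np.isfinite(self.vm)) or np.any(self.vm < 0):
                raise CountsValidationError("vm must be finite and non-negative")

    @property
    def n_epochs(self) -> int:
        return len(self.axis1)

    @property
    def duration_seconds(self) -> int:
        return self.n_epochs * self.epoch_length

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=self.n_epochs, freq=f"{self.epoch_length}s"
        )

    def seconds_of_day(self) -> np.ndarray:
        """Clock seconds since local midnight for each epoch start."""
        t0 = self.start_time
        offset = t0.hour * 3600 + t0.minute * 60 + t0.second
        return (offset + np.arange(self.n_epochs, dtype=np.int64) * self.epoch_length) % 86400

    def day_index(self) -> np.ndarray:
        """Index of the calendar day (0 = day of the first epoch) per epoch."""
        t0 = self.start_time
        offset = t0.hour * 3600 + t0.minute * 60 + t0.second
        return (offset + np.arange(self.n_epochs, dtype=np.int64) * self.epoch_length) // 86400

    def day_dates(self) -> list:
        """Calendar dates covered by the recording, in order."""
        first = self.start_time.date()
        n_days = int(self.day_index()[-1]) + 1 if self.n_epochs else 0
        return [first + timedelta(days=d) for d in range(n_days)]

    def axis(self, which: str) -> np.ndarray:
        """Counts for an axis selector: 'vertical' (axis1) or 'vm'."""
        if which in ("vertical", "axis1"):
            return self.axis1
        if which in ("vm", "vector_magnitude"):
            return self.vm
        raise ValueError(f"unknown axis selector {which!r}")

    def equals(self, other: "CountSeries") -> bool:
        return (
            self.start_time == other.start_time
            and self.epoch_length == other.epoch_length
            and self.subject_id == other.subject_id
            and np.array_equal(self.axis1, other.axis1)
            and np.array_equal(self.axis2, other.axis2)
            and np.array_equal(self.axis3, other.axis3)
            and np.allclose(self.vm, other.vm, rtol=1e-9, atol=0)
        )

    def with_subject(self, subject_id: str) -> "CountSeries":
        return replace(self, subject_id=subject_id)


def compute_vm(a1: np.ndarray, a2: np.ndarray, a3: np.ndarray) -> np.ndarray:
    a1 = np.asarray(a1, dtype=np.float64)
    a2 = np.asarray(a2, dtype=np.float64)
    a3 = np.asarray(a3, dtype=np.float64)
    return np.sqrt(a1 * a1 + a2 * a2 + a3 * a3)


def _as_count_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind == "f":
        if not np.all(np.isfinite(arr)):
            raise CountsValidationError(f"{name} contains non-finite values")
        rounded = np.rint(arr)
        if not np.array_equal(rounded, arr):
            raise CountsValidationError(f"{name} contains non-integer counts")
        arr = rounded
    arr = arr.astype(np.int64, copy=False)
    if arr.ndim != 1:
        raise CountsValidationError(f"{name} must be one-dimensional")
    if arr.size and arr.min() < 0:
        raise CountsValidationError(f"{name} contains negative counts")
    return arr


def read_counts_csv(
    path,
    *,
    start_time: datetime | str | None = None,
    epoch_length: int | None = None,
    subject_id: str = "",
) -> CountSeries:
    """Read a counts CSV into a :class:`CountSeries`.

    By default the two-line header supplies the start time and epoch length.
    Headerless three/four-column files are accepted when ``start_time`` and
    ``epoch_length`` are given explicitly. ``vm`` is always recomputed from
    the axes.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    if start_time is None or epoch_length is None:
        if len(lines) < 3:
            raise CountsFormatError(f"{path}: missing header block")
        header = {}
        for ln in lines[:2]:
            parts = ln.split(",", 1)
            if len(parts) != 2:
                raise CountsFormatError(f"{path}: malformed header line {ln!r}")
            header[parts[0].strip()] = parts[1].strip()
        for key in ("start_time", "epoch_length"):
            if key not in header:
                raise CountsFormatError(f"{path}: header missing field {key!r}")
        start_time = datetime.strptime(header["start_time"], TIME_FORMAT)
        try:
            epoch_length = int(header["epoch_length"])
        except ValueError as exc:
            raise CountsFormatError(f"{path}: epoch_length is not an integer") from exc
        body = "\n".join(lines[2:])
        header_row = 0
    else:
        if isinstance(start_time, str):
            start_time = datetime.strptime(start_time, TIME_FORMAT)
        body = text
        header_row = None

    df = pd.read_csv(io.StringIO(body), header=header_row, dtype=str)
    if header_row is None:
        ncol = df.shape[1]
        if ncol == 3:
            df.columns = ["axis1", "axis2", "axis3"]
        elif ncol == 4:
            df.columns = ["timestamp", "axis1", "axis2", "axis3"]
        elif ncol == 5:
            df.columns = ["timestamp", "axis1", "axis2", "axis3", "vm"]
        else:
            raise CountsFormatError(f"{path}: expected 3-5 columns, found {ncol}")
    for col in ("axis1", "axis2", "axis3"):
        if col not in df.columns:
            raise CountsFormatError(f"{path}: missing column {col!r}")
    axes = []
    for col in ("axis1", "axis2", "axis3"):
        raw = df[col]
        if raw.isna().any():
            row = int(raw.isna().idxmax()) + 1
            raise CountsFormatError(f"{path}: inconsistent row width at data row {row}")
        try:
            vals = pd.to_numeric(raw)
        except (ValueError, TypeError) as exc:
            raise CountsValidationError(f"{path}: non-numeric count in {col}") from exc
        arr = np.asarray(vals)
        bad = ~np.isfinite(arr) | (arr < 0) | (np.rint(arr) != arr)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise CountsValidationError(
                f"{path}: negative or non-integer count in {col} at data row {row}"
            )
        axes.append(arr.astype(np.int64))
    return CountSeries(
        start_time=start_time,
        epoch_length=int(epoch_length),
        axis1=axes[0],
        axis2=axes[1],
        axis3=axes[2],
        subject_id=subject_id,
    )


def write_counts_csv(series: CountSeries, path) -> None:
    """Write a :class:`CountSeries` re-readable by :func:`read_counts_csv`.

    Integer axis values are written undecorated; vm with two decimals
    (vendor convention). Output is byte-deterministic for a given series.
    """
    ts = series.timestamps().strftime(TIME_FORMAT)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"start_time,{series.start_time.strftime(TIME_FORMAT)}\n")
        fh.write(f"epoch_length,{series.epoch_length}\n")
        fh.write("timestamp,axis1,axis2,axis3,vm\n")
        for t, a1, a2, a3, v in zip(
            ts, series.axis1, series.axis2, series.axis3, series.vm
        ):
            fh.write(f"{t},{a1},{a2},{a3},{v:.2f}\n")


def write_table_csv(df: pd.DataFrame, path) -> None:
    """Persist a tidy mask/summary table deterministically."""
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.6g")
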