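"""Reading and writing 1 Hz leg-accelerometer logger exports.

Loggers record vertical-axis (Y) acceleration in g at 1 Hz, one CSV per horse
per 24 h observation period.  Files are parsed onto a strict one-second grid
from the first to the last timestamp; grid seconds without a row become
explicit missing samples (NaN) rather than being silently dropped.

Vendor export layouts vary, so the reader takes a :class:`LoggerDialect`
describing column names, separator and decimal mark.  The canonical dialect
(the one the package writes) is a header row with columns ``timestamp``
(ISO-8601 local clock time) and ``y_acc_g``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd


class LoggerFormatError(ValueError):
    """Raised for unparseable or inconsistent logger files."""


@dataclass(frozen=True)
class LoggerDialect:
    """Describes how to map a logger CSV export onto the canonical columns."""

    timestamp_col: str = "timestamp"
    accel_col: str = "y_acc_g"
    sep: str = ","
    decimal: str = "."
    float_fmt: str = "%.6f"

    def with_overrides(self, **kwargs) -> "LoggerDialect":
        return replace(self, **kwargs)


CANONICAL_DIALECT = LoggerDialect()


@dataclass
class AccelSeries:
    """A regular 1 Hz series of vertical-axis acceleration for one horse-period.

    Attributes
    ----------
    horse_id
        Opaque identifier of the animal.
    start_time
        Local clock time of the first sample (no timezone arithmetic is ever
        applied; day/night windows are defined on the local clock).
    y_accel
        Acceleration in g, one value per second; ``NaN`` marks missing samples.
    sample_rate_hz
        Fixed at 1.
    meta
        Free-form provenance (missing-data fraction, gap-fill counts, ...).
    """

    horse_id: str
    start_time: pd.Timestamp
    y_accel: np.ndarray
    sample_rate_hz: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y_accel = np.asarray(self.y_accel, dtype=float)
        self.start_time = pd.Timestamp(self.start_time)
        if self.y_accel.ndim != 1 or self.y_accel.size < 1:
            raise ValueError("y_accel must be a non-empty 1-d array")
        if self.sample_rate_hz != 1:
            raise ValueError("only 1 Hz series are supported")

    def __len__(self) -> int:
        return self.y_accel.size

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.y_accel)

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    def timestamps(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(np.arange(len(self)), unit="s")

    @property
    def end_time(self) -> pd.Timestamp:
        """Exclusive end of the series (one second past the last sample)."""
        return self.start_time + pd.Timedelta(seconds=len(self))


def read_logger_csv(
    path: str | Path,
    dialect: LoggerDialect = CANONICAL_DIALECT,
    horse_id: str | None = None,
) -> AccelSeries:
    """Parse a logger CSV export into an :class:`AccelSeries` on a strict 1 s grid.

    Rows are placed on the second grid spanned by the first and last
    timestamps.  Seconds with no row become NaN; two rows mapping to the same
    second are an error, as are timestamps that go backwards.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.sep, decimal=dialect.decimal)
    for col in (dialect.timestamp_col, dialect.accel_col):
        if col not in df.columns:
            raise LoggerFormatError(f"{path.name}: missing column {col!r} (found {list(df.columns)})")
    if len(df) == 0:
        raise LoggerFormatError(f"{path.name}: no data rows")

    ts = pd.to_datetime(df[dialect.timestamp_col], errors="coerce")
    bad = ts.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise LoggerFormatError(
            f"{path.name}: unparseable timestamp at data row {row}: "
            f"{df[dialect.timestamp_col].iloc[row]!r}"
        )
    if not ts.is_monotonic_increasing:
        drops = np.flatnonzero(np.diff(ts.to_numpy()) < np.timedelta64(0))
        raise LoggerFormatError(f"{path.name}: timestamps not monotone (first decrease after data row {int(drops[0])})")

    t0 = ts.iloc[0].floor("s")
    offsets = ((ts - t0).dt.total_seconds().round()).astype(np.int64).to_numpy()
    if np.any(np.diff(offsets) == 0):
        row = int(np.flatnonzero(np.diff(offsets) == 0)[0]) + 1
        raise LoggerFormatError(f"{path.name}: timestamp collision at data row {row} ({ts.iloc[row]})")

    n = int(offsets[-1]) + 1
    y = np.full(n, np.nan)
    y[offsets] = pd.to_numeric(df[dialect.accel_col], errors="coerce").to_numpy(dtype=float)

    series = AccelSeries(
        horse_id=horse_id if horse_id is not None else path.stem,
        start_time=t0,
        y_accel=y,
    )
    series.meta["source"] = str(path)
    series.meta["frac_missing"] = float(np.isnan(y).mean())
    if series.meta["frac_missing"] > 0.10:
        series.meta["high_missingness"] = True
    return series


def write_logger_csv(
    series: AccelSeries,
    path: str | Path,
    dialect: LoggerDialect = CANONICAL_DIALECT,
) -> Path:
    """Serialize an :class:`AccelSeries` back to logger CSV.

    Missing samples are written as absent rows, so read → write → read is the
    identity on the grid (values round-trip at the dialect's printed
    precision).
    """
    path = Path(path)
    keep = ~series.missing
    ts = series.timestamps()[keep]
    out = pd.DataFrame(
        {
            dialect.timestamp_col: ts.strftime("%Y-%m-%dT%H:%M:%S"),
            dialect.accel_col: series.y_accel[keep],
        }
    )
    out.to_csv(path, sep=dialect.sep, decimal=dialect.decimal, index=False, float_format=dialect.float_fmt)
    return path


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/stop (exclusive) index pairs of each maximal True run."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def fill_short_gaps(series: AccelSeries, max_gap_s: int = 5) -> AccelSeries:
    """Carry the last observed value forward across missing runs of <= ``max_gap_s``.

    Longer runs, and a leading run with no preceding value, stay missing.  The
    number of filled samples is recorded in ``meta['n_gap_filled']``.  Short
    sensor dropouts should not fragment bouts downstream; long dropouts
    instead reduce the observed-time denominator of the per-hour metrics.
    """
    if max_gap_s < 0:
        raise ValueError("max_gap_s must be >= 0")
    mask = series.missing
    if mask.all():
        raise ValueError("series is entirely missing; nothing to fill")
    y = series.y_accel.copy()
    n_filled = 0
    for start, stop in _nan_runs(mask):
        if start == 0 or (stop - start) > max_gap_s:
            continue
        y[start:stop] = y[start - 1]
        n_filled += stop - start
    out = AccelSeries(series.horse_id, series.start_time, y, meta=dict(series.meta))
    out.meta["n_gap_filled"] = n_filled + out.meta.get("n_gap_filled", 0)
    out.meta["frac_missing"] = float(np.isnan(y).mean())
    return out
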