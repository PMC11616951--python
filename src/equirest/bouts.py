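"""Bout segmentation and per-hour day/night lying metrics.

A bout is a maximal run of one posture state in the smoothed per-second
sequence; a missing-data run terminates the current bout.  Outcomes are
aggregated over two clock-defined observation windows — day 08:30-16:00
(7.5 h, the experimental-condition phase) and night 17:00-07:30 of the next
day (14.5 h, all horses stabled individually) — and normalized per hour of
observation so the two windows are comparable:

* ``n_bouts_per_h``  — lying bouts overlapping the window / observed hours,
* ``lying_h_per_h``  — lying hours inside the window / observed hours.

Observed hours count non-missing seconds only, so sensor dropouts shrink the
denominator instead of biasing the rate.  Bouts straddling a window edge are
clipped for duration and counted if their overlap is positive.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .posture import LYING, MISSING, PostureSeries


@dataclass(frozen=True)
class Bout:
    """One maximal run of a single posture state; ``end`` is exclusive."""

    state: int
    start_idx: int
    end_idx: int
    start: pd.Timestamp | None = None
    end: pd.Timestamp | None = None

    @property
    def duration_s(self) -> int:
        return self.end_idx - self.start_idx


@dataclass(frozen=True)
class WindowSpec:
    """A clock-defined observation window; NIGHT spans midnight."""

    label: str
    start_clock: dt.time
    end_clock: dt.time

    @property
    def spans_midnight(self) -> bool:
        return self.end_clock <= self.start_clock

    @property
    def nominal_hours(self) -> float:
        start = self.start_clock.hour * 3600 + self.start_clock.minute * 60 + self.start_clock.second
        end = self.end_clock.hour * 3600 + self.end_clock.minute * 60 + self.end_clock.second
        span = (end - start) % 86400
        if span == 0:
            raise ValueError("window has zero length")
        return span / 3600.0

    def bounds(self, base_date: dt.date) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Absolute [start, end) for the window anchored on ``base_date``.

        A midnight-spanning window starts on ``base_date`` and ends on the
        following day (the night is attributed to the evening's date).
        """
        start = pd.Timestamp.combine(pd.Timestamp(base_date), self.start_clock)
        end = pd.Timestamp.combine(pd.Timestamp(base_date), self.end_clock)
        if self.spans_midnight:
            end += pd.Timedelta(days=1)
        return start, end


DAY_WINDOW = WindowSpec("DAY", dt.time(8, 30), dt.time(16, 0))
NIGHT_WINDOW = WindowSpec("NIGHT", dt.time(17, 0), dt.time(7, 30))


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """(state, start, stop) for each maximal run."""
    if states.size == 0:
        return []
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [states.size]))
    return [(int(states[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def segment_bouts(posture: PostureSeries) -> list[Bout]:
    """Segment a (smoothed) posture series into maximal same-state bouts.

    Missing runs are not bouts; they terminate the bout in progress, so the
    returned list tiles exactly the observed (non-missing) time.
    """
    ts = posture.timestamps() if posture.start_time is not None else None
    bouts = []
    for state, a, b in _runs(posture.states):
        if state == MISSING:
            continue
        bouts.append(
            Bout(
                state=state,
                start_idx=a,
                end_idx=b,
                start=ts[a] if ts is not None else None,
                end=ts[b - 1] + pd.Timedelta(seconds=1) if ts is not None else None,
            )
        )
    return bouts


def bouts_to_frame(bouts: list[Bout], horse_id: str = "") -> pd.DataFrame:
    from .posture import STATE_NAMES

    return pd.DataFrame(
        {
            "horse_id": horse_id,
            "state": [STATE_NAMES[b.state] for b in bouts],
            "start": [b.start for b in bouts],
            "end": [b.end for b in bouts],
            "duration_s": [b.duration_s for b in bouts],
        }
    )


def compute_metrics(
    bouts: list[Bout],
    window: WindowSpec,
    posture: PostureSeries,
    base_date: dt.date | None = None,
    condition: str | None = None,
) -> dict:
    """Per-hour lying metrics of one horse-period within one clock window.

    Parameters
    ----------
    bouts
        Output of :func:`segment_bouts` for the same series.
    window
        DAY or NIGHT specification.
    posture
        The smoothed series the bouts came from (supplies the time grid and
        the missing mask for the observed-hours denominator).
    base_date
        Calendar date anchoring the window; defaults to the series start
        date.  Nights are attributed to the evening's date.
    condition
        Optional experimental-condition label copied into the output row.

    Returns
    -------
    dict with keys ``horse_id, date, condition, window, n_bouts_per_h,
    lying_h_per_h, observed_h, lying_s, n_lying_bouts``.
    """
    if posture.start_time is None:
        raise ValueError("posture series needs a start_time to locate clock windows")
    if base_date is None:
        base_date = posture.start_time.date()
    w_start, w_end = window.bounds(base_date)

    t0 = posture.start_time
    i0 = max(0, int(np.ceil((w_start - t0).total_seconds())))
    i1 = min(len(posture), int(np.ceil((w_end - t0).total_seconds())))
    if i1 <= i0:
        raise ValueError(f"window {window.label} on {base_date} does not overlap the series")

    seg = posture.states[i0:i1]
    observed_s = int((seg != MISSING).sum())
    if observed_s == 0:
        raise ValueError(f"window {window.label} on {base_date} has zero observed time")
    observed_h = observed_s / 3600.0
    lying_s = int((seg == LYING).sum())

    n_lying = sum(1 for b in bouts if b.state == LYING and b.start_idx < i1 and b.end_idx > i0)

    return {
        "horse_id": posture.horse_id,
        "date": pd.Timestamp(base_date).date().isoformat(),
        "condition": condition,
        "window": window.label,
        "n_bouts_per_h": n_lying / observed_h,
        "lying_h_per_h": (lying_s / 3600.0) / observed_h,
        "observed_h": observed_h,
        "lying_s": lying_s,
        "n_lying_bouts": n_lying,
    }


def period_metrics(
    posture: PostureSeries,
    base_date: dt.date | None = None,
    condition: str | None = None,
    windows: tuple[WindowSpec, ...] = (DAY_WINDOW, NIGHT_WINDOW),
) -> pd.DataFrame:
    """Segment one smoothed horse-period and compute metrics for each window."""
    bouts = segment_bouts(posture)
    rows = [compute_metrics(bouts, w, posture, base_date=base_date, condition=condition) for w in windows]
    return pd.DataFrame(rows)
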