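"""Crossover-schedule construction for the three daytime housing conditions.

Each horse passes through the three conditions — alone in an indoor box
(``BOX``), alone on an outdoor paddock (``ALONE``), in pairs on the paddock
(``PAIRS``) — once per repetition, in a randomized order.  With three
conditions there are six possible orders; across all horse x repetition
sequences the orders are balanced so each is used at least
``floor(n_sequences / 6)`` times, surplus uses being allotted to randomly
chosen orders.  A horse never repeats the same order across repetitions.

For ten horses and two repetitions this reproduces the reference layout:
20 sequences over 60 horse-periods, every order used at least three times and
exactly two orders used four times.
"""

from __future__ import annotations

import datetime as dt
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS: tuple[str, str, str] = ("BOX", "ALONE", "PAIRS")
PERMUTATIONS: tuple[tuple[str, str, str], ...] = tuple(itertools.permutations(CONDITIONS))


class InfeasibleDesignError(ValueError):
    """Raised when no schedule can satisfy the balance constraints."""


@dataclass
class CrossoverSchedule:
    """Long-format schedule: one row per horse-period.

    ``entries`` columns: ``horse_id, repetition, position, condition, date``.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"horse_id", "repetition", "position", "condition", "date"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"schedule missing columns {sorted(missing)}")

    @property
    def n_periods(self) -> int:
        return len(self.entries)

    def sequences(self) -> pd.DataFrame:
        """One row per horse x repetition with the condition order as a tuple."""
        seq = (
            self.entries.sort_values(["horse_id", "repetition", "position"])
            .groupby(["horse_id", "repetition"], sort=True)["condition"]
            .agg(tuple)
            .rename("sequence")
            .reset_index()
        )
        return seq

    def permutation_counts(self) -> dict[tuple[str, str, str], int]:
        counts = dict.fromkeys(PERMUTATIONS, 0)
        for s in self.sequences()["sequence"]:
            if s in counts:
                counts[s] += 1
        return counts

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CrossoverSchedule":
        return cls(pd.read_csv(path, dtype={"horse_id": str}))


@dataclass
class ValidationReport:
    checks: list[tuple[str, bool, str]] = field(default_factory=list)
    permutation_counts: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def summary(self) -> str:
        lines = [f"[{'ok' if ok else 'FAIL'}] {name}: {detail}" for name, ok, detail in self.checks]
        lines.append("sequence uses: " + ", ".join(f"{'-'.join(p)}={c}" for p, c in self.permutation_counts.items()))
        return "\n".join(lines)


def _assign_sequences(n_horses: int, n_reps: int, rng: np.random.Generator) -> list[list[int]]:
    """Balanced allocation of the 6 condition orders to horse x repetition slots.

    Degree-sequence realization: process orders by decreasing use count and
    hand all copies of an order to the currently most-needy horses (random
    tie-breaks).  Each order is processed once, so no horse can repeat it;
    the most-needy-first rule realizes any feasible degree sequence, and the
    sequence here is feasible exactly when n_reps <= 6 and no order is
    needed more than n_horses times.
    """
    n_seq = n_horses * n_reps
    if n_reps > len(PERMUTATIONS):
        raise InfeasibleDesignError(
            f"{n_reps} distinct sequences per horse requested but only {len(PERMUTATIONS)} orders exist"
        )
    base, extra = divmod(n_seq, 6)
    counts = np.full(6, base, dtype=int)
    counts[rng.choice(6, size=extra, replace=False)] += 1
    if counts.max() > n_horses:
        raise InfeasibleDesignError(
            f"an order would need {counts.max()} uses but only {n_horses} horses are available"
        )

    need = np.full(n_horses, n_reps, dtype=int)
    assigned: list[list[int]] = [[] for _ in range(n_horses)]
    type_order = np.lexsort((rng.random(6), -counts))
    for p in type_order:
        c = int(counts[p])
        if c == 0:
            continue
        # c most-needy horses, ties randomized
        pri = np.lexsort((rng.random(n_horses), -need))
        take = pri[:c]
        if need[take].min() < 1:  # pragma: no cover - excluded by feasibility checks
            raise InfeasibleDesignError("allocation failed; constraints unsatisfiable")
        for h in take:
            assigned[int(h)].append(int(p))
            need[int(h)] -= 1
    for seqs in assigned:  # randomize which repetition gets which order
        rng.shuffle(seqs)
    return assigned


def generate_schedule(
    n_horses: int,
    n_reps: int,
    seed: int | np.random.Generator | None = None,
    dates: list[dt.date] | None = None,
    horses_per_date: int = 3,
    start_date: dt.date = dt.date(2022, 3, 1),
    step_days: int = 3,
) -> CrossoverSchedule:
    """Generate a balanced, reproducible crossover schedule.

    Parameters
    ----------
    n_horses, n_reps
        Study size; the reference design is 10 horses x 2 repetitions
        (60 24-h periods).
    seed
        RNG seed or Generator; the allocation is randomized but reproducible.
    dates
        Optional explicit list of available observation dates, consumed in
        order.  If absent, synthetic dates are generated: horses are grouped
        ``horses_per_date`` at a time, each group observed together on one
        date per repetition x position, dates spaced ``step_days`` apart from
        ``start_date``.  Sharing dates across horses is what makes the
        horse x calendar-date random-effect structure crossed rather than
        nested.
    """
    if n_horses < 1 or n_reps < 1:
        raise ValueError("n_horses and n_reps must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    assigned = _assign_sequences(n_horses, n_reps, rng)

    horse_ids = [f"H{h + 1:02d}" for h in range(n_horses)]
    group_of = np.repeat(np.arange(n_horses), 1)
    order = rng.permutation(n_horses)
    group_of[order] = np.arange(n_horses) // max(1, horses_per_date)
    n_groups = int(group_of.max()) + 1

    n_dates_needed = n_reps * 3 * n_groups
    if dates is not None:
        if len(dates) < n_dates_needed:
            raise ValueError(f"need {n_dates_needed} dates, got {len(dates)}")
        date_list = [pd.Timestamp(d).date() for d in dates[:n_dates_needed]]
    else:
        date_list = [start_date + dt.timedelta(days=step_days * k) for k in range(n_dates_needed)]

    rows = []
    for h in range(n_horses):
        for r in range(n_reps):
            perm = PERMUTATIONS[assigned[h][r]]
            for pos in range(3):
                slot = (r * 3 + pos) * n_groups + int(group_of[h])
                rows.append(
                    {
                        "horse_id": horse_ids[h],
                        "repetition": r + 1,
                        "position": pos + 1,
                        "condition": perm[pos],
                        "date": date_list[slot].isoformat(),
                    }
                )
    entries = pd.DataFrame(rows).sort_values(["date", "horse_id"], kind="stable").reset_index(drop=True)
    return CrossoverSchedule(entries)


def validate_schedule(schedule: CrossoverSchedule) -> ValidationReport:
    """Check every schedule invariant; report-only, never raises."""
    report = ValidationReport()
    e = schedule.entries

    per_cell = e.groupby(["horse_id", "repetition"])["condition"].agg(lambda c: sorted(c) == sorted(CONDITIONS))
    report.checks.append(
        (
            "each horse x repetition uses every condition once",
            bool(per_cell.all()),
            f"{int((~per_cell).sum())} violating cells" if not per_cell.all() else "all cells complete",
        )
    )

    seqs = schedule.sequences()
    dup = seqs.groupby("horse_id")["sequence"].agg(lambda s: len(set(s)) == len(s))
    report.checks.append(
        (
            "repetition sequences differ within horse",
            bool(dup.all()),
            f"horses with identical sequences: {sorted(dup.index[~dup])}" if not dup.all() else "all distinct",
        )
    )

    counts = schedule.permutation_counts()
    n_seq = len(seqs)
    floor_req = n_seq // 6
    min_count = min(counts.values()) if counts else 0
    report.checks.append(
        (
            f"each of the 6 orders used >= floor(n_seq/6) = {floor_req} times",
            min_count >= floor_req,
            f"min count {min_count}",
        )
    )
    report.permutation_counts = counts
    return report
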