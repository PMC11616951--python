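"""Ground-truthed synthetic data for every pipeline stage.

Two generators:

* :func:`simulate_trace` — a two-state alternating-renewal posture process
  (standing/lying sojourns drawn from lognormal or exponential laws) rendered
  as a 1 Hz vertical-axis acceleration trace: about -1 g standing, about 0 g
  lying, plus Gaussian sensor noise.  The exact bout list is returned with
  the trace, so classification and segmentation can be checked against
  ground truth.
* :func:`simulate_experiment` — outcome tables with exactly the statistical
  structure the mixed model assumes: six condition x window cell means on
  the log scale, crossed Gaussian horse and calendar-date intercepts, and
  Gaussian residual noise, laid over a crossover schedule.

Default experiment parameters encode the factor structure reported for young
stabled horses: night lying duration ~11x day, slightly more day bouts than
night, and modest increases from indoor box to outdoor paddock (alone, then
in pairs).  Default variances are sized from the width of the published
factor confidence intervals on the log scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bouts import DAY_WINDOW, NIGHT_WINDOW, Bout
from .design import CrossoverSchedule
from .io import AccelSeries
from .lmm import CELLS, CONDITION_LEVELS, WINDOW_LEVELS
from .posture import LYING, STANDING


@dataclass(frozen=True)
class TraceSimParams:
    """Alternating-renewal trace parameters.

    Sojourn means are in seconds; ``sdlog`` is the lognormal log-scale sd
    (right-skewed bouts).  ``min_bout_s`` rejects draws below a floor, which
    pins every true bout above the smoothing window when needed for exact
    recovery checks.  Signal levels reflect a leg-mounted vertical-axis
    sensor: gravity-aligned (about -1 g) standing, horizontal (about 0 g)
    lying.
    """

    mean_standing_bout_s: float = 5400.0
    mean_lying_bout_s: float = 1500.0
    bout_dist: str = "lognormal"  # or "exponential"
    sdlog: float = 0.6
    standing_level_g: float = -1.0
    lying_level_g: float = 0.0
    noise_sd_g: float = 0.03
    duration_s: int = 86400
    min_bout_s: float = 0.0
    start_state: int | None = None  # None = random by stationary fraction
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mean_standing_bout_s <= 0 or self.mean_lying_bout_s <= 0:
            raise ValueError("mean bout durations must be positive")
        if self.duration_s < 1:
            raise ValueError("duration_s must be >= 1")
        if self.bout_dist not in ("lognormal", "exponential"):
            raise ValueError("bout_dist must be 'lognormal' or 'exponential'")
        if self.noise_sd_g < 0:
            raise ValueError("noise_sd_g must be >= 0")
        if not self.standing_level_g < -0.75 < self.lying_level_g:
            raise ValueError("signal levels must straddle the -0.75 g threshold")

    def replace(self, **kwargs) -> "TraceSimParams":
        return dataclasses.replace(self, **kwargs)


def _draw_bout(mean: float, params: TraceSimParams, rng: np.random.Generator) -> float:
    while True:
        if params.bout_dist == "lognormal":
            mu = np.log(mean) - 0.5 * params.sdlog**2
            d = rng.lognormal(mu, params.sdlog)
        else:
            d = rng.exponential(mean)
        d = max(1.0, round(d))
        if d >= max(1.0, params.min_bout_s):
            return d


def simulate_trace(
    params: TraceSimParams = TraceSimParams(),
    horse_id: str = "SIM",
    start_time: str | pd.Timestamp = "2022-03-01 08:00:00",
    rng: np.random.Generator | None = None,
) -> tuple[AccelSeries, list[Bout]]:
    """Simulate one accelerometer trace and return it with its true bout list.

    Bouts alternate standing/lying until ``duration_s`` is tiled; the last
    bout is truncated at the end of the trace.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    p_lying = params.mean_lying_bout_s / (params.mean_lying_bout_s + params.mean_standing_bout_s)
    state = params.start_state if params.start_state is not None else (LYING if rng.random() < p_lying else STANDING)

    start_time = pd.Timestamp(start_time)
    states = np.empty(params.duration_s, dtype=np.int8)
    truth: list[Bout] = []
    t = 0
    while t < params.duration_s:
        mean = params.mean_lying_bout_s if state == LYING else params.mean_standing_bout_s
        d = int(_draw_bout(mean, params, rng))
        end = min(t + d, params.duration_s)
        if params.duration_s - end < params.min_bout_s:
            # absorb a tail shorter than the floor so every true bout honours it
            end = params.duration_s
        states[t:end] = state
        truth.append(
            Bout(
                state=state,
                start_idx=t,
                end_idx=end,
                start=start_time + pd.Timedelta(seconds=t),
                end=start_time + pd.Timedelta(seconds=end),
            )
        )
        t = end
        state = STANDING if state == LYING else LYING

    levels = np.where(states == LYING, params.lying_level_g, params.standing_level_g)
    y = levels + (rng.normal(0.0, params.noise_sd_g, size=params.duration_s) if params.noise_sd_g > 0 else 0.0)
    series = AccelSeries(horse_id=horse_id, start_time=start_time, y_accel=y)
    series.meta["simulated"] = True
    return series, truth


# ---------------------------------------------------------------------------
# experiment-level generator


def _factor_cell_means(day_box: float, nightday_factor: float,
                       condition_factors: tuple[float, float, float]) -> np.ndarray:
    """Log cell means from a day BOX level and multiplicative factors.

    ``condition_factors`` are (BOX, ALONE, PAIRS) multipliers applied in both
    windows (no interaction); ``nightday_factor`` multiplies night cells.
    Order follows :data:`equirest.lmm.CELLS`.
    """
    mu = np.empty(6)
    for k, (c, w) in enumerate(CELLS):
        f = condition_factors[CONDITION_LEVELS.index(c)]
        level = day_box * f * (nightday_factor if w == "NIGHT" else 1.0)
        mu[k] = np.log(level)
    return mu


@dataclass(frozen=True)
class ExperimentSimParams:
    """Cell means (log scale, CELLS order) and variance components.

    The default parameterizes the lying-duration outcome: night/day factor
    11.25 over a day-box level of 0.018 h/h, condition factors
    (1, 1.39, 1.38), and log-scale variances sized from published interval
    widths (large residual day-to-day variability within horses).  Use
    :meth:`bouts_defaults` for the bout-count outcome (day/night factor 1.21,
    condition factors (1, 1.08, 1.17), tighter variances).
    """

    n_horses: int = 10
    n_reps: int = 2
    cell_means: tuple[float, ...] = tuple(_factor_cell_means(0.018, 11.25, (1.0, 1.39, 1.38)))
    sigma2_horse: float = 0.3
    sigma2_date: float = 0.1
    sigma2_resid: float = 2.0
    outcome: str = "lying_h_per_h"
    offset: float = 0.0  # inverse-transform constant: y = exp(v) - offset
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.cell_means) != 6:
            raise ValueError("cell_means must have 6 entries (3 conditions x 2 windows)")
        if min(self.sigma2_horse, self.sigma2_date, self.sigma2_resid) < 0:
            raise ValueError("variances must be >= 0")

    @classmethod
    def duration_defaults(cls, **overrides) -> "ExperimentSimParams":
        return cls(**overrides)

    @classmethod
    def bouts_defaults(cls, **overrides) -> "ExperimentSimParams":
        """Bout-count outcome: more bouts by day (factor 1.21) than night."""
        defaults = dict(
            cell_means=tuple(_factor_cell_means(0.40, 1.0 / 1.21, (1.0, 1.08, 1.17))),
            sigma2_horse=0.10,
            sigma2_date=0.05,
            sigma2_resid=0.30,
            outcome="n_bouts_per_h",
        )
        defaults.update(overrides)
        return cls(**defaults)

    def replace(self, **kwargs) -> "ExperimentSimParams":
        return dataclasses.replace(self, **kwargs)

    def cell_mean(self, condition: str, window: str) -> float:
        return self.cell_means[CELLS.index((condition, window))]


def simulate_experiment(
    design: CrossoverSchedule,
    params: ExperimentSimParams = ExperimentSimParams(),
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate an outcome table under the mixed model, over a schedule.

    One row per horse-period x window.  Returns the table and a truth record
    (cell means, variances, and the drawn horse/date effects).
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    entries = design.entries
    horses = sorted(entries["horse_id"].astype(str).unique())
    dates = sorted(entries["date"].astype(str).unique())
    b_horse = dict(zip(horses, rng.normal(0.0, np.sqrt(params.sigma2_horse), len(horses))))
    b_date = dict(zip(dates, rng.normal(0.0, np.sqrt(params.sigma2_date), len(dates))))

    rows = []
    for _, ent in entries.iterrows():
        for window in WINDOW_LEVELS:
            v = (
                params.cell_mean(ent["condition"], window)
                + b_horse[str(ent["horse_id"])]
                + b_date[str(ent["date"])]
                + rng.normal(0.0, np.sqrt(params.sigma2_resid))
            )
            y = max(0.0, float(np.exp(v) - params.offset))
            rows.append(
                {
                    "horse_id": ent["horse_id"],
                    "date": ent["date"],
                    "condition": ent["condition"],
                    "window": window,
                    params.outcome: y,
                    "observed_h": DAY_WINDOW.nominal_hours if window == "DAY" else NIGHT_WINDOW.nominal_hours,
                }
            )
    table = pd.DataFrame(rows)
    truth = {
        "cell_means": dict(zip([f"{c}:{w}" for c, w in CELLS], params.cell_means)),
        "sigma2_horse": params.sigma2_horse,
        "sigma2_date": params.sigma2_date,
        "sigma2_resid": params.sigma2_resid,
        "offset": params.offset,
        "b_horse": b_horse,
        "b_date": b_date,
    }
    return table, truth
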