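"""Per-second posture classification from vertical leg acceleration.

A leg-mounted sensor reads about -1 g on its vertical (Y) axis while the
horse stands (axis aligned with gravity) and about 0 g while it lies (axis
horizontal).  Classification is therefore a single threshold: samples with
acceleration lower than -0.75 g are standing, samples at or above it lying.
The raw per-second labels are then smoothed with a running median over a
31-sample (31 s) window; for a binary sequence the running median over an odd
window is exactly the majority vote, which removes isolated misclassified
seconds without displacing genuine posture transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import AccelSeries

STANDING: int = 0
LYING: int = 1
MISSING: int = -1

STATE_NAMES = {STANDING: "STANDING", LYING: "LYING", MISSING: "MISSING"}


@dataclass(frozen=True)
class ClassifierConfig:
    """Threshold and smoothing-window settings.

    Defaults (-0.75 g threshold, 31-sample window at 1 Hz) are the reference
    settings for leg-mounted loggers on horses.
    """

    threshold_g: float = -0.75
    window_samples: int = 31
    sample_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        if self.window_samples < 1 or self.window_samples % 2 == 0:
            raise ValueError("window_samples must be an odd positive integer")
        if self.sample_rate_hz != 1:
            raise ValueError("only 1 Hz data is supported")


@dataclass
class PostureSeries:
    """Per-second posture states aligned to a source :class:`AccelSeries`."""

    states: np.ndarray  # int8 over {STANDING, LYING, MISSING}
    horse_id: str = ""
    start_time: pd.Timestamp | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1:
            raise ValueError("states must be 1-d")
        bad = ~np.isin(self.states, (STANDING, LYING, MISSING))
        if bad.any():
            raise ValueError(f"invalid state code {self.states[bad][0]}")

    def __len__(self) -> int:
        return self.states.size

    def timestamps(self) -> pd.DatetimeIndex:
        if self.start_time is None:
            raise ValueError("series has no start_time")
        return self.start_time + pd.to_timedelta(np.arange(len(self)), unit="s")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.timestamps().strftime("%Y-%m-%dT%H:%M:%S"),
             "state": [STATE_NAMES[s] for s in self.states]}
        )


def _threshold_states(y: np.ndarray, threshold_g: float) -> np.ndarray:
    states = np.full(y.shape, MISSING, dtype=np.int8)
    obs = ~np.isnan(y)
    # boundary value goes to LYING: "lower than threshold" is standing
    states[obs & (y >= threshold_g)] = LYING
    states[obs & (y < threshold_g)] = STANDING
    return states


def _majority_smooth(states: np.ndarray, window: int) -> np.ndarray:
    """Centered majority vote, truncated at the edges, missing excluded.

    Ties resolve to STANDING; a window with no non-missing votes is MISSING.
    Vectorized with cumulative sums, O(n).
    """
    n = states.size
    h = window // 2
    lying = np.concatenate(([0], np.cumsum(states == LYING)))
    standing = np.concatenate(([0], np.cumsum(states == STANDING)))
    lo = np.clip(np.arange(n) - h, 0, n)
    hi = np.clip(np.arange(n) + h + 1, 0, n)
    n_lying = lying[hi] - lying[lo]
    n_standing = standing[hi] - standing[lo]
    out = np.where(n_lying > n_standing, LYING, STANDING).astype(np.int8)
    out[(n_lying == 0) & (n_standing == 0)] = MISSING
    return out


def threshold_classify(series: AccelSeries, config: ClassifierConfig = ClassifierConfig()) -> PostureSeries:
    """Assign LYING/STANDING per sample by thresholding; no smoothing applied."""
    states = _threshold_states(series.y_accel, config.threshold_g)
    return PostureSeries(states, horse_id=series.horse_id, start_time=series.start_time,
                         meta={"threshold_g": config.threshold_g})


def smooth_majority(posture: PostureSeries, config: ClassifierConfig = ClassifierConfig()) -> PostureSeries:
    """Running-median (majority-vote) smoothing over ``config.window_samples``.

    Output states are MISSING exactly where every vote in the (truncated)
    window is missing; in particular isolated dropouts shorter than the
    half-window are voted over rather than propagated.
    """
    smoothed = _majority_smooth(posture.states, config.window_samples)
    # a sample that was missing in the source stays missing: smoothing must
    # not manufacture posture at dropouts, only vote over neighbours
    smoothed[posture.states == MISSING] = MISSING
    return PostureSeries(smoothed, horse_id=posture.horse_id, start_time=posture.start_time,
                         meta={**posture.meta, "window_samples": config.window_samples})


class PostureClassifier(TransformerMixin, BaseEstimator):
    """Threshold + majority-vote posture classifier as a stateless transformer.

    Parameters
    ----------
    threshold_g : float, default -0.75
        Samples below this acceleration (in g) are standing, at or above it
        lying.
    window_samples : int, default 31
        Odd width of the centered majority-vote smoothing window, in samples
        (seconds at 1 Hz).
    smooth : bool, default True
        Apply the majority filter after thresholding.

    Examples
    --------
    >>> clf = PostureClassifier()
    >>> clf.fit_transform(np.full(40, -1.0)).max()
    0
    """

    def __init__(self, threshold_g: float = -0.75, window_samples: int = 31, smooth: bool = True):
        self.threshold_g = threshold_g
        self.window_samples = window_samples
        self.smooth = smooth

    def _config(self) -> ClassifierConfig:
        return ClassifierConfig(threshold_g=self.threshold_g, window_samples=self.window_samples)

    def fit(self, X=None, y=None) -> "PostureClassifier":
        self._config()  # validate parameters
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        """Classify a 1-d acceleration array (NaN = missing) into state codes."""
        cfg = self._config()
        y = np.asarray(X, dtype=float).ravel()
        states = _threshold_states(y, cfg.threshold_g)
        if self.smooth:
            out = _majority_smooth(states, cfg.window_samples)
            out[states == MISSING] = MISSING
            return out
        return states

    def classify(self, series: AccelSeries) -> PostureSeries:
        """AccelSeries-level convenience wrapper around :meth:`transform`."""
        cfg = self._config()
        raw = threshold_classify(series, cfg)
        return smooth_majority(raw, cfg) if self.smooth else raw
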