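"""Threshold classification and majority-vote smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equirest.io import AccelSeries
from equirest.posture import (
    LYING,
    MISSING,
    STANDING,
    ClassifierConfig,
    PostureClassifier,
    smooth_majority,
    threshold_classify,
)


def brute_force_majority(states: np.ndarray, window: int) -> np.ndarray:
    """Independent per-position oracle: count votes in the truncated centered
    window, excluding missing; ties -> STANDING; no votes -> MISSING."""
    n = states.size
    h = window // 2
    out = np.empty(n, dtype=np.int8)
    for i in range(n):
        win = states[max(0, i - h) : min(n, i + h + 1)]
        n_ly = int((win == LYING).sum())
        n_st = int((win == STANDING).sum())
        if n_ly == 0 and n_st == 0:
            out[i] = MISSING
        else:
            out[i] = LYING if n_ly > n_st else STANDING
    out[states == MISSING] = MISSING
    return out


def _series(y):
    return AccelSeries("h", "2022-03-05T08:00:00", np.asarray(y, dtype=float))


class TestThreshold:
    @pytest.mark.parametrize(
        "value, state",
        [(-1.0, STANDING), (0.0, LYING), (-0.75, LYING), (-0.76, STANDING), (-0.74, LYING)],
    )
    def test_threshold_rule_and_boundary(self, value, state):
        """Below -0.75 g the leg is vertical (standing); at or above, lying."""
        ps = threshold_classify(_series([value]))
        assert ps.states[0] == state

    def test_missing_stays_missing(self):
        ps = threshold_classify(_series([-1.0, np.nan, 0.0]))
        np.testing.assert_array_equal(ps.states, [STANDING, MISSING, LYING])


class TestSmoothMajority:
    def test_constant_series_unchanged(self):
        ps = threshold_classify(_series(np.full(100, -1.0)))
        out = smooth_majority(ps)
        assert (out.states == STANDING).all()

    def test_isolated_flip_removed(self):
        y = np.full(100, -1.0)
        y[50] = 0.0  # a single lying second inside standing
        out = smooth_majority(threshold_classify(_series(y)))
        assert (out.states == STANDING).all()

    def test_transition_preserved_at_boundary(self):
        y = np.concatenate([np.full(60, -1.0), np.full(60, 0.0)])
        out = smooth_majority(threshold_classify(_series(y)))
        np.testing.assert_array_equal(out.states[:60], STANDING)
        np.testing.assert_array_equal(out.states[60:], LYING)

    def test_running_median_equals_majority_vote(self, rng):
        """For binary data the median over an odd window is the majority state."""
        from equirest.posture import PostureSeries
        from numpy.lib.stride_tricks import sliding_window_view

        states = rng.integers(0, 2, size=400).astype(np.int8)
        cfg = ClassifierConfig(window_samples=31)
        smoothed = smooth_majority(PostureSeries(states), cfg).states
        h = 15

        med = np.median(sliding_window_view(states, 31), axis=1)
        np.testing.assert_array_equal(smoothed[h:-h], med.astype(np.int8))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(st.sampled_from([0, 1, -1]), min_size=1, max_size=200),
        st.sampled_from([3, 5, 9, 31]),
    )
    def test_equivalence_with_brute_force_oracle(self, states, window):
        from equirest.posture import PostureSeries

        states = np.array(states, dtype=np.int8)
        cfg = ClassifierConfig(window_samples=window)
        got = smooth_majority(PostureSeries(states), cfg).states
        np.testing.assert_array_equal(got, brute_force_majority(states, window))

    def test_interior_runs_at_least_half_window_on_bout_signals(self, rng):
        """On bout-structured input (true runs >= window) with sparse isolated
        misclassified samples, smoothing leaves no interior run shorter than
        (w+1)/2.  (This is not true of arbitrary binary noise: a strictly
        alternating series is a fixed point of any centered majority vote.)"""
        from equirest.posture import PostureSeries

        for _ in range(50):
            states = _bout_signal_with_isolated_flips(rng, n_runs=8, min_run=31, window=31)
            out = smooth_majority(PostureSeries(states), ClassifierConfig(window_samples=31)).states
            runs = _run_lengths(out)
            if len(runs) > 2:
                assert min(runs[1:-1]) >= 16

    def test_fixed_points_are_signals_with_runs_of_at_least_16(self, rng):
        """A binary signal whose runs all reach (w+1)/2 is a root of the
        window-w majority filter: smoothing returns it unchanged."""
        from equirest.posture import PostureSeries

        for _ in range(30):
            lengths = rng.integers(16, 60, size=10)
            state = int(rng.integers(0, 2))
            parts = []
            for ln in lengths:
                parts.append(np.full(ln, state, dtype=np.int8))
                state = 1 - state
            states = np.concatenate(parts)
            out = smooth_majority(PostureSeries(states), ClassifierConfig(window_samples=31)).states
            np.testing.assert_array_equal(out, states)

    def test_idempotent_on_well_separated_runs(self):
        from equirest.posture import PostureSeries

        states = np.concatenate([np.zeros(40), np.ones(31), np.zeros(50), np.ones(35)]).astype(np.int8)
        out = smooth_majority(PostureSeries(states), ClassifierConfig(window_samples=31)).states
        np.testing.assert_array_equal(out, states)

    def test_missing_excluded_from_votes_and_preserved(self):
        from equirest.posture import PostureSeries

        states = np.array([1, 1, -1, 1, 1], dtype=np.int8)
        out = smooth_majority(PostureSeries(states), ClassifierConfig(window_samples=3)).states
        np.testing.assert_array_equal(out, [1, 1, -1, 1, 1])


def _run_lengths(states):
    change = np.flatnonzero(np.diff(states)) + 1
    edges = np.concatenate(([0], change, [states.size]))
    return np.diff(edges)


def _bout_signal_with_isolated_flips(rng, n_runs=8, min_run=31, window=31):
    """Alternating runs of >= min_run samples plus isolated single-sample
    flips separated by more than one window width."""
    parts = []
    state = int(rng.integers(0, 2))
    for _ in range(n_runs):
        parts.append(np.full(int(rng.integers(min_run, 4 * min_run)), state, dtype=np.int8))
        state = 1 - state
    states = np.concatenate(parts)
    pos = int(rng.integers(0, window + 1))
    while pos < states.size:
        states[pos] = 1 - states[pos]
        pos += window + 1 + int(rng.integers(0, 3 * window))
    return states


class TestPostureClassifierEstimator:
    def test_sklearn_params_round_trip(self):
        clf = PostureClassifier(threshold_g=-0.6, window_samples=5)
        assert PostureClassifier(**clf.get_params()).get_params() == clf.get_params()

    def test_even_window_rejected_on_fit(self):
        with pytest.raises(ValueError, match="odd"):
            PostureClassifier(window_samples=30).fit()

    def test_transform_matches_series_path(self, rng):
        y = rng.normal(-0.5, 0.6, size=500)
        clf = PostureClassifier().fit()
        series_states = clf.classify(_series(y)).states
        np.testing.assert_array_equal(clf.transform(y), series_states)
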