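"""Delayed-coincidence detectors: delays, membrane maximum, threshold sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scorploc import Dataset, StimulusPosition, Trial, generate_dataset
from scorploc.coincidence import (
    CoincidenceDetector,
    build_detectors,
    classify,
    estimate_speed,
    fit_threshold,
    fit_thresholds,
    v_max,
)
from scorploc.wave_sim import NoiseModel, WaveParams


class TestEstimateSpeed:
    def test_recovers_generator_speed(self, noiseless_ds):
        assert estimate_speed(noiseless_ds) == pytest.approx(126.0, rel=1e-3)

    def test_constant_sensor_shift_leaves_slope(self, noiseless_ds):
        shifted = Dataset(
            noiseless_ds.sensor_array,
            [
                Trial(t.trial_id, t.position, t.spike_times + 5000, t.onset)
                for t in noiseless_ds.trials
            ],
            dict(noiseless_ds.meta),
        )
        assert estimate_speed(shifted) == pytest.approx(
            estimate_speed(noiseless_ds), rel=1e-12
        )

    def test_equal_times_degenerate(self, array):
        tr = Trial(0, StimulusPosition(0, 100), np.full(8, 100))
        with pytest.raises(ValueError, match="degenerate"):
            estimate_speed(Dataset(array, [tr], {}))


class TestBuildDetectors:
    def test_delays_nonnegative_min_zero(self, array, grid):
        for det in build_detectors(array, grid, 126.0):
            assert np.all(det.delays_us >= 0)
            assert det.delays_us.min() == 0.0

    def test_arrival_plus_delay_constant(self, array, grid):
        for det in build_detectors(array, grid, 126.0):
            d = np.linalg.norm(array.positions - det.position.cartesian, axis=1)
            t_p = d * 1000.0 / 126.0
            total = t_p + det.delays_us
            np.testing.assert_allclose(total, total[0], rtol=1e-12)

    def test_delays_match_geometry_at_800mm_90deg(self, array):
        det = build_detectors(array, [StimulusPosition(90.0, 800.0)], 126.0)[0]
        d = np.linalg.norm(array.positions - [0.0, 800.0], axis=1)
        expected = (d.max() - d) * 1000.0 / 126.0
        np.testing.assert_allclose(det.delays_us, expected, rtol=1e-12)


class TestVmax:
    def test_perfect_coincidence_reaches_sensor_count(self, array):
        det = CoincidenceDetector(StimulusPosition(0, 100), np.zeros(8), 100.0)
        tr = Trial(0, StimulusPosition(0, 100), np.full(8, 500))
        assert v_max(det, tr) == pytest.approx(8.0)

    def test_two_spike_half_decay(self):
        tau = 100.0
        det = CoincidenceDetector(StimulusPosition(0, 100), np.zeros(2), tau)
        dt = tau * np.log(2.0)
        tr = Trial(0, StimulusPosition(0, 100), np.array([0, round(dt)]))
        # the second spike decays to one half (up to the 1 µs timestamp grid)
        assert v_max(det, tr) == pytest.approx(1 + np.exp(-round(dt) / tau), abs=1e-12)
        assert v_max(det, tr) == pytest.approx(1.5, abs=5e-3)

    def test_matches_dense_grid_oracle(self, array):
        rng = np.random.default_rng(4)
        for _ in range(10):
            delays = rng.uniform(0, 500, 8)
            times = rng.integers(0, 2000, 8)
            det = CoincidenceDetector(StimulusPosition(0, 100), delays, 100.0)
            tr = Trial(0, StimulusPosition(0, 100), times)
            a = times + delays
            tgrid = np.union1d(np.arange(a.min(), a.max() + 1, 0.1), a)
            v = np.where(
                tgrid[None, :] >= a[:, None],
                np.exp(-(tgrid[None, :] - a[:, None]) / 100.0),
                0.0,
            ).sum(axis=0)
            assert v_max(det, tr) == pytest.approx(v.max(), rel=1e-6)

    def test_shift_invariance(self, array):
        det = CoincidenceDetector(
            StimulusPosition(0, 100), np.linspace(0, 300, 8), 100.0
        )
        t = np.array([10, 40, 90, 160, 250, 360, 490, 640])
        assert v_max(det, Trial(0, det.position, t)) == pytest.approx(
            v_max(det, Trial(0, det.position, t + 10_000))
        )


def _brute_force_error(values, labels):
    """Exhaustive minimization of FN + FP over all candidate thresholds."""
    candidates = np.concatenate([values, [values.max() + 1.0]])
    best = None
    for theta in candidates:
        fires = values >= theta
        e = int(np.sum(~fires & (labels == 1)) + np.sum(fires & (labels == -1)))
        best = e if best is None else min(best, e)
    return best


class TestFitThreshold:
    def test_perfect_separation(self):
        fit = fit_threshold(np.array([5.0, 6.0, 1.0, 2.0]), np.array([1, 1, -1, -1]))
        assert fit.error == 0
        assert 2.0 < fit.theta <= 5.0

    def test_all_positive(self):
        fit = fit_threshold(np.array([3.0, 1.0, 2.0]), np.array([1, 1, 1]))
        assert fit.error == 0
        assert fit.theta <= 1.0

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 25)
        values = np.round(rng.uniform(0, 8, n), 1)  # ties on purpose
        labels = rng.choice([-1, 1], n)
        if not ((labels == 1).any() and (labels == -1).any()):
            labels[0], labels[-1] = 1, -1
        fit = fit_threshold(values, labels)
        assert fit.error == _brute_force_error(values, labels)
        # the achieved error is recomputable from the stored pairs
        fires = values >= fit.theta
        assert fit.error == int(
            np.sum(~fires & (labels == 1)) + np.sum(fires & (labels == -1))
        )


class TestClassify:
    def test_noiseless_self_detector_wins(self, array, grid, noiseless_ds):
        bank = build_detectors(array, grid, 126.0)
        fit_thresholds(bank, noiseless_ds)
        for tr in noiseless_ds.trials[::37]:
            assert classify(bank, tr).label == tr.position.label

    def test_shift_invariance(self, array, grid, noiseless_ds):
        bank = build_detectors(array, grid, 126.0)
        tr = noiseless_ds.trials[100]
        shifted = Trial(tr.trial_id, tr.position, tr.spike_times + 4321, tr.onset)
        assert classify(bank, tr).label == classify(bank, shifted).label

    def test_off_grid_trial_is_total(self, array, grid):
        bank = build_detectors(array, grid, 126.0)
        ds = generate_dataset(
            array,
            [StimulusPosition(30.0, 333.0)],
            1,
            WaveParams(126.0),
            NoiseModel.noiseless(),
            seed=0,
        )
        pred = classify(bank, ds.trials[0])
        assert pred.label in {g.label for g in grid}

    def test_vmax_bounded_by_sensor_count(self, array, grid, jitter5_ds):
        bank = build_detectors(array, grid, 126.0)
        for tr in jitter5_ds.trials[::53]:
            for det in bank[::7]:
                assert v_max(det, tr) <= 8.0 + 1e-12
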