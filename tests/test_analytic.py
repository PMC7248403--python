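"""Closed-form multilateration: algebra, exact recovery, conditioning."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from scorploc import SensorArray, StimulusPosition, generate_dataset, tdoa
from scorploc.analytic import (
    DegenerateGeometryError,
    build_system,
    conditioning_profile,
    solve,
    solve_trial,
)
from scorploc.wave_sim import NoiseModel, WaveParams, first_spike_times


def _noiseless_tdoa(array, pos, speed):
    t = first_spike_times(array, pos, WaveParams(speed))
    return t[0] - t[1:]


class TestBuildSystem:
    def test_zero_tdoa_zeroes_time_columns(self, array):
        A, _ = build_system(array, np.zeros(7))
        assert np.all(A[:, 2] == 0)
        assert np.all(A[:, 3] == 0)

    def test_row_count(self, array):
        A, B = build_system(array, np.zeros(7))
        assert A.shape == (7, 4)
        assert B.shape == (7,)

    def test_rows_satisfy_distance_identity(self, array):
        """Symbolic check: the true X = [u, v, c·d, c²] satisfies A·X = B row by row.

        Each row encodes d_1² − d_j² expanded with d_j = d_1 + c·ΔT_1j, so
        plugging in the exact geometry must give an exact identity.
        """
        rng = np.random.default_rng(3)
        for _ in range(10):
            pos = StimulusPosition(rng.uniform(0, 360), rng.uniform(150, 900))
            c = rng.uniform(50, 300)
            A, B = build_system(array, _noiseless_tdoa(array, pos, c))
            u, v = pos.cartesian / 1000.0
            d1 = np.linalg.norm(pos.cartesian - array.positions[0]) / 1000.0
            X = np.array([u, v, c * d1, c**2])
            np.testing.assert_allclose(A @ X, B, atol=1e-12)


class TestSolve:
    def test_exact_recovery_all_grid_positions(self, array, grid):
        for pos in grid:
            s = solve(array, _noiseless_tdoa(array, pos, 126.0))
            assert s.valid
            np.testing.assert_allclose([s.u, s.v], pos.cartesian, atol=1e-6)
            assert s.c == pytest.approx(126.0, abs=1e-6)
            d_true = np.linalg.norm(pos.cartesian - array.positions[0])
            assert s.d == pytest.approx(d_true, abs=1e-6)

    def test_equals_nonlinear_least_squares_oracle(self, array):
        rng = np.random.default_rng(8)
        for _ in range(20):
            pos = StimulusPosition(rng.uniform(0, 360), rng.uniform(200, 800))
            c_true = rng.uniform(80, 280)
            dt = _noiseless_tdoa(array, pos, c_true)
            s = solve(array, dt)

            def resid(x):
                u, v, c = x
                d = np.linalg.norm(array.positions - [u, v], axis=1)
                return (d[0] - d[1:]) * 1000.0 / c - dt

            best = None
            for a0 in (45.0, 135.0, 225.0, 315.0):
                x0 = [*StimulusPosition(a0, 400.0).cartesian, 150.0]
                fit = least_squares(resid, x0, method="lm")
                if best is None or fit.cost < best.cost:
                    best = fit
            np.testing.assert_allclose([s.u, s.v], best.x[:2], atol=1e-3)
            assert s.c == pytest.approx(best.x[2], abs=1e-3)

    def test_zero_tdoa_is_degenerate(self, array):
        with pytest.raises(DegenerateGeometryError):
            solve(array, np.zeros(7))

    def test_circular_array_is_degenerate(self):
        ang = np.radians(45.0 * np.arange(8))
        circ = SensorArray(np.column_stack([150 * np.cos(ang), 150 * np.sin(ang)]))
        pos = StimulusPosition(30.0, 500.0)
        dt = _noiseless_tdoa(circ, pos, 126.0)
        # for a circular ring the four columns are linearly dependent in the
        # noiseless far field only approximately; the canonical degenerate
        # case is the all-zero TDOA of a central source
        with pytest.raises(DegenerateGeometryError):
            solve(circ, np.zeros(7))
        assert np.linalg.cond(build_system(circ, dt)[0]) > 1e3

    def test_shift_and_permutation_invariance(self, array):
        pos = StimulusPosition(222.0, 444.0)
        ds = generate_dataset(
            array, [pos], 1, WaveParams(126.0), NoiseModel.noiseless(), seed=0
        )
        tr = ds.trials[0]
        s0 = solve_trial(array, tr)
        # constant time shift
        shifted = type(tr)(tr.trial_id, tr.position, tr.spike_times + 777, tr.onset)
        s1 = solve_trial(array, shifted)
        assert (s0.u, s0.v, s0.c) == (s1.u, s1.v, s1.c)
        # permute the non-reference sensors together with their spike times
        perm = [0, 3, 1, 2, 6, 5, 7, 4]
        arr_p = SensorArray(array.positions[perm])
        tr_p = type(tr)(tr.trial_id, tr.position, tr.spike_times[perm], tr.onset)
        s2 = solve_trial(arr_p, tr_p)
        np.testing.assert_allclose([s0.u, s0.v, s0.c], [s2.u, s2.v, s2.c], rtol=1e-9)

    def test_noise_can_flag_invalid_speed(self, array):
        ds = generate_dataset(
            array,
            [StimulusPosition(90.0, 800.0)],
            1,
            WaveParams(126.0),
            NoiseModel(jitter_sigma=200.0, sensor_bias=np.zeros(8)),
            seed=0,
        )
        s = solve_trial(array, ds.trials[0])
        assert not s.valid
        assert s.c is None and s.d is None


class TestConditioning:
    def test_profile_structure(self, array, grid):
        cond = conditioning_profile(array, grid, WaveParams(126.0))
        by_angle = {}
        for g, c in zip(grid, cond):
            by_angle.setdefault(g.angle_deg, []).append(c)
        means = {a: np.mean(v) for a, v in by_angle.items()}
        assert np.all(np.isfinite(cond))
        # worst conditioning along the minor axis (90/270), mirror-symmetric
        worst = max(means, key=means.get)
        assert worst in (90.0, 270.0)
        assert means[90.0] == pytest.approx(means[270.0], rel=1e-6)
        assert means[45.0] == pytest.approx(means[315.0], rel=1e-6)
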