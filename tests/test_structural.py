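"""STDP kernels, structural re-spawning, and EI-network specialization."""

from dataclasses import replace

import numpy as np
import pytest

from scorploc.structural_plasticity import (
    EiConfig,
    StdpParams,
    alpha_current,
    respawn_check,
    stdp_dtau,
    stdp_dw,
    train,
    weight_decay,
)


class TestWeightStdp:
    def test_coincident_pair_potentiates_at_full_rate(self):
        p = StdpParams()
        assert stdp_dw(5.0, 5.0, p) == pytest.approx(p.a_w_plus)

    def test_causal_window_decay(self):
        p = StdpParams()
        assert stdp_dw(0.0, p.tau_plus, p) == pytest.approx(p.a_w_plus * np.exp(-1))

    def test_depression_decays_by_default(self):
        p = StdpParams()
        near = stdp_dw(1.0, 0.0, p)
        far = stdp_dw(50.0, 0.0, p)
        assert near < 0 and far < 0
        assert abs(far) < abs(near)

    def test_printed_depression_grows_with_lag(self):
        p = StdpParams()
        d = stdp_dw(p.tau_minus, 0.0, p, as_printed=True)
        assert abs(d) == pytest.approx(p.a_w_minus * np.e)

    def test_weight_decay_examples(self):
        p = StdpParams(a_w_plus=0.01, a_w_minus=0.01, eta_decay=0.01)  # kappa = 1
        assert weight_decay(1.0, p) == pytest.approx(0.99)
        assert weight_decay(0.0, p) == 0.0
        w = 1.0
        for _ in range(100):
            w = weight_decay(w, p)
        assert w == pytest.approx(0.99**100)

    def test_runaway_decay_config_rejected(self):
        with pytest.raises(ValueError):
            StdpParams(a_w_plus=1.0, a_w_minus=0.01, eta_decay=0.5)  # kappa*eta >= 1


class TestTauStdp:
    def test_zero_at_offset(self):
        p = StdpParams()
        assert stdp_dtau(p.s_offset, p) == 0.0

    def test_peak_value_at_tau_star(self):
        p = StdpParams()
        assert stdp_dtau(p.tau_star, p) == pytest.approx(p.a_tau)

    def test_sign_follows_linear_factor(self):
        p = StdpParams()
        for dt in np.linspace(-5, 10, 31):
            assert np.sign(stdp_dtau(dt, p)) == np.sign(dt - p.s_offset)

    def test_early_channels_grow_late_channels_shrink(self):
        """Sign-convention oracle: with delta_t = t_post - t_pre, an early
        pre-spike (large delta_t) lengthens its time constant and a late
        pre-spike (small delta_t) shortens it."""
        p = StdpParams()
        t_post = 3.0
        early_pre, late_pre = 0.0, 2.9
        assert stdp_dtau(t_post - early_pre, p) > 0
        assert stdp_dtau(t_post - late_pre, p) < 0


class TestAlphaSynapse:
    def test_peak_normalization(self):
        t0, tau = 1.0, 2.3
        peak = alpha_current(np.array([t0 + tau]), t0, 1.0, tau)[0]
        assert peak == pytest.approx(1.0, abs=1e-9)

    def test_causal(self):
        assert alpha_current(np.array([0.5]), 1.0, 1.0, 2.0)[0] == 0.0


class TestRespawn:
    def test_healthy_synapses_untouched(self):
        rng = np.random.default_rng(0)
        w = np.full(8, 0.5)
        tau = np.full(8, 2.0)
        w2, tau2, spawned = respawn_check(w, tau, rng, threshold=0.1)
        assert not spawned
        assert w2 is w and tau2 is tau

    def test_decayed_synapses_replaced_positive(self):
        rng = np.random.default_rng(0)
        w = np.full(8, 0.01)
        tau = np.full(8, 2.0)
        w2, tau2, spawned = respawn_check(w, tau, rng, threshold=0.1)
        assert spawned
        assert np.all(w2 > 0) and np.all(tau2 > 0)
        assert not np.array_equal(w2, w)

    def test_seeded_respawn_is_reproducible(self):
        draws = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            out = [
                respawn_check(np.zeros(8), np.full(8, 2.0), rng, threshold=0.1)[0]
                for _ in range(3)
            ]
            draws.append(np.concatenate(out))
        np.testing.assert_array_equal(draws[0], draws[1])


class TestTraining:
    def test_four_pattern_capture_is_modal(self, four_patterns):
        counts = [
            train(four_patterns, EiConfig(), presentations=20, seed=sd).captured_patterns
            for sd in range(5)
        ]
        assert sorted(counts, reverse=True)[len(counts) // 2] == 4  # modal outcome

    def test_weights_stay_bounded(self, four_patterns):
        cfg = EiConfig()
        r = train(four_patterns, cfg, presentations=20, seed=1)
        assert np.all(r.weights >= 0)
        assert np.all(r.weights <= cfg.w_max)
        assert np.all(r.tau_syn > 0)

    def test_single_neuron_responds_earlier_over_training(self, four_patterns):
        cfg = replace(
            EiConfig(),
            n_exc=1,
            n_inh=1,
            theta_step=0.0,
            theta_miss_step=1.0,
            theta_init_above=25.0,
        )
        r = train([four_patterns[0]], cfg, presentations=30, seed=2)
        lat = [t for t, ring, _ in sorted(r.raster) if ring == "exc"]
        # latency within each presentation window decreases overall
        dur = max(t for t, ring, _ in r.raster if ring == "input") + 1
        rel = [t % _presentation_period(r) for t in lat]
        assert rel[-1] < rel[0]
        assert np.mean(np.diff(rel) <= 1e-9) > 0.8  # mostly non-increasing

    def test_thirty_two_pattern_run_reports_without_error(self, array, grid):
        from scorploc import generate_dataset
        from scorploc.wave_sim import NoiseModel, WaveParams

        pats = generate_dataset(
            array, grid, 1, WaveParams(126.0), NoiseModel(jitter_sigma=20.0), seed=3
        ).trials
        cfg = replace(EiConfig(), n_exc=32, n_inh=8)
        r = train(pats, cfg, presentations=5, seed=0)
        assert 0 <= r.captured_patterns <= 32
        assert isinstance(r.one_to_one, bool)


def _presentation_period(result) -> float:
    """Infer the fixed per-presentation time offset from the raster."""
    inputs = sorted(t for t, ring, k in result.raster if ring == "input" and k == 0)
    return inputs[1] - inputs[0]
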