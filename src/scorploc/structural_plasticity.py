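"""Self-organizing excitatory–inhibitory network with plastic weights and
synaptic time constants.

Each excitatory neuron receives the 8 input channels through alpha synapses

    I_syn(t) = Ī_syn · (t − t₀)/τ_syn · exp(1 − (t − t₀)/τ_syn)

(peak Ī_syn exactly one τ_syn after the pre-spike; a pre-spike adds the
synaptic weight w to the peak amplitude).  Three plasticity processes act on
every post-synaptic spike:

- **weight STDP** — potentiation a_w⁺·e^{(t_pre−t_post)/τ⁺} for causal pairs,
  a decaying depression window otherwise, plus a multiplicative event-driven
  decay w ← w(1 − κη) that prevents the usual additive-STDP bimodal runaway;
- **time-constant STDP** — Δτ = a_τ·(Δt−s)·e^{−|Δt−s|/(τ*−s)}/((τ*−s)e^{−1})
  with Δt = t_post − t_pre, so channels spiking early in the sequence grow
  slower (longer-lasting) synapses and late channels grow faster ones,
  pulling the post-spike earlier;
- **structural plasticity** — when a neuron's mean input weight falls below a
  threshold, all 8 synapses are deleted and re-spawned with Gaussian random
  weights and time constants.

Competition comes from inhibitory interneurons (any excitatory spike drives
them; they hyperpolarize all excitatory neurons) and from FEAST-style
adaptive thresholds: a neuron's threshold steps up on each own spike and
relaxes toward a floor between presentations, equalizing capture rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from scorploc.arena import Trial

__all__ = [
    "StdpParams",
    "EiConfig",
    "StructuralTrainResult",
    "stdp_dw",
    "weight_decay",
    "stdp_dtau",
    "respawn_check",
    "alpha_current",
    "train",
]


@dataclass(frozen=True)
class StdpParams:
    """Plasticity constants (weights in units of w_max, times in ms)."""

    a_w_plus: float = 0.02
    a_w_minus: float = 0.02
    tau_plus: float = 10.0
    tau_minus: float = 10.0
    eta_decay: float = 0.01  # event-driven decay rate, << 1
    a_tau: float = 0.02  # ms per post spike; slow relative to the tau range
    tau_star: float = 2.0  # ms, peak of the time-constant kernel
    s_offset: float = 0.5  # ms, zero crossing; tau_star > s_offset

    def __post_init__(self) -> None:
        if self.tau_star <= self.s_offset:
            raise ValueError("tau_star must exceed s_offset")
        if self.kappa * self.eta_decay >= 1.0:
            raise ValueError("kappa * eta_decay must be < 1")

    @property
    def kappa(self) -> float:
        return self.a_w_plus / self.a_w_minus


def stdp_dw(
    t_pre: float, t_post: float, params: StdpParams, as_printed: bool = False
) -> float:
    """Weight change for one pre/post spike pair.

    Causal pairs (t_pre <= t_post) potentiate with an exponentially decaying
    window.  Anti-causal pairs depress; by default the depression window also
    decays with lag.  ``as_printed=True`` switches the depression exponent
    sign so its magnitude *grows* with lag (the literal formula, kept
    switchable for comparison; it diverges for large lags).
    """
    lag = t_pre - t_post
    if lag <= 0:
        return params.a_w_plus * math.exp(lag / params.tau_plus)
    if as_printed:
        return -params.a_w_minus * math.exp(lag / params.tau_minus)
    return -params.a_w_minus * math.exp(-lag / params.tau_minus)


def weight_decay(w: float | np.ndarray, params: StdpParams) -> float | np.ndarray:
    """Event-driven multiplicative decay w ← w(1 − κη), fixed point at 0."""
    return w * (1.0 - params.kappa * params.eta_decay)


def stdp_dtau(delta_t: float, params: StdpParams) -> float:
    """Synaptic time-constant change for Δt = t_post − t_pre.

    Zero at Δt = s_offset, peak value a_tau at Δt = tau_star (the normalizer
    (τ*−s)·e⁻¹ cancels there), sign equal to sign(Δt − s_offset): channels
    that fired early relative to the post spike (large Δt) get longer time
    constants, late channels get shorter ones.
    """
    p = params
    x = delta_t - p.s_offset
    scale = (p.tau_star - p.s_offset) * math.exp(-1.0)
    return p.a_tau * x * math.exp(-abs(x) / (p.tau_star - p.s_offset)) / scale


def respawn_check(
    w: np.ndarray,
    tau_syn: np.ndarray,
    rng: np.random.Generator,
    threshold: float,
    spawn_w: tuple[float, float] = (0.5, 0.2),
    spawn_tau: tuple[float, float] = (2.0, 1.0),
    min_w: float = 0.05,
    min_tau: float = 0.3,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Replace all synapses of one neuron when its mean weight has decayed away.

    If mean(w) >= threshold the arrays are returned unchanged (bit-identical);
    otherwise a full fresh set is drawn from clipped Gaussians.
    """
    if w.mean() >= threshold:
        return w, tau_syn, False
    n = w.shape[0]
    w_new = np.clip(rng.normal(*spawn_w, size=n), min_w, None)
    tau_new = np.clip(rng.normal(*spawn_tau, size=n), min_tau, None)
    return w_new, tau_new, True


def alpha_current(t_ms: np.ndarray, t0_ms: float, w: float, tau_syn: float) -> np.ndarray:
    """Alpha-kernel EPSC with peak amplitude w at t0 + tau_syn (zero before t0)."""
    u = np.asarray(t_ms, dtype=float) - t0_ms
    out = w * (u / tau_syn) * np.exp(1.0 - u / tau_syn)
    return np.where(u >= 0, out, 0.0)


@dataclass(frozen=True)
class EiConfig:
    """EI network constants (mV, ms; currents in units of w_max·Ī_syn)."""

    n_exc: int = 4
    n_inh: int = 2
    n_inputs: int = 8
    w_max: float = 1.0
    stdp: StdpParams = StdpParams()
    # LIF; the membrane is fast (below the pattern's sub-ms structure) so
    # the response depends on the coincidence structure of the EPSCs, not
    # just their total charge
    E_L: float = -70.0
    tau_m: float = 0.5
    v_reset: float = -70.0
    refractory: float = 5.0
    R_m: float = 20.0  # mV per unit synaptic current
    # adaptive threshold
    theta_floor: float = -55.0  # mV, relaxation target / lowest useful threshold
    theta_init_above: float = 100.0  # mV above E_L: start unresponsive, decrease on misses
    theta_init_spread: float = 2.0  # mV, uniform random jitter on the init
    theta_step: float = 2.0  # mV increase on each own spike
    theta_relax: float = 1.0  # optional per-presentation relaxation toward the floor
    theta_miss_step: float = 4.0  # mV decrease (all neurons) when nobody fires
    # WTA coupling
    w_exc_to_inh: float = 5.0
    w_inh_to_exc: float = 8.0
    tau_syn_inh: float = 30.0
    # synapse birth distributions (initialization and re-spawn)
    spawn_w: tuple[float, float] = (0.5, 0.2)  # Gaussian (mean, sd) in w_max units
    spawn_tau: tuple[float, float] = (0.6, 0.3)  # Gaussian (mean, sd) ms
    min_tau: float = 0.2  # ms clip
    # structural plasticity
    respawn_threshold: float = 0.1  # of w_max
    respawn_every: int = 10  # presentations
    # simulation
    dt: float = 0.1
    t_pad: float = 25.0  # ms simulated past the last input spike

    def __post_init__(self) -> None:
        if self.n_exc < 1 or self.n_inh < 0:
            raise ValueError("need at least one excitatory neuron")


@dataclass
class StructuralTrainResult:
    """Final synapses, adaptation traces, and capture statistics."""

    config: EiConfig
    weights: np.ndarray  # (n_exc, n_inputs)
    tau_syn: np.ndarray  # (n_exc, n_inputs) ms
    thresholds: np.ndarray  # (n_exc,) final mV
    threshold_trace: np.ndarray  # (presentations, n_exc)
    winner_log: list[tuple[int, int | None]]  # (pattern index, winning exc or None)
    raster: list[tuple[float, str, int]]  # (global time ms, ring, neuron id)
    eval_responses: list[list[int]]  # per pattern: exc neurons spiking, frozen pass
    respawn_count: int = 0

    @property
    def captured_patterns(self) -> int:
        """Patterns answered by exactly one excitatory neuron in the frozen pass."""
        return sum(1 for r in self.eval_responses if len(r) == 1)

    @property
    def one_to_one(self) -> bool:
        """True when every pattern has exactly one responder and all differ."""
        if any(len(r) != 1 for r in self.eval_responses):
            return False
        winners = [r[0] for r in self.eval_responses]
        return len(set(winners)) == len(winners)


def _pattern_ms(trial: Trial) -> np.ndarray:
    t = trial.spike_times.astype(float) / 1000.0
    return t - t.min()


def _run_presentation(
    pattern_ms: np.ndarray,
    w: np.ndarray,
    tau: np.ndarray,
    theta: np.ndarray,
    cfg: EiConfig,
) -> tuple[list[tuple[float, int]], list[tuple[float, int]]]:
    """Clock-driven run of one pattern; returns (exc spikes, inh spikes)."""
    dt = cfg.dt
    n_steps = int((pattern_ms.max() + cfg.t_pad) / dt) + 1
    grid = np.arange(n_steps) * dt
    # precompute total input current per exc neuron over the window
    u = grid[None, None, :] - pattern_ms[None, :, None]  # (1, n_in, n_steps)
    x = np.clip(u, 0.0, None) / tau[:, :, None]
    I_in = np.where(u >= 0, w[:, :, None] * x * np.exp(1.0 - x), 0.0).sum(axis=1)
    decay_m = math.exp(-dt / cfg.tau_m)
    decay_inh = math.exp(-dt / cfg.tau_syn_inh)
    refr_steps = int(round(cfg.refractory / dt))

    v_e = np.full(cfg.n_exc, cfg.E_L)
    ref_e = np.zeros(cfg.n_exc, dtype=int)
    v_i = np.full(cfg.n_inh, cfg.E_L)
    ref_i = np.zeros(cfg.n_inh, dtype=int)
    i_ei = 0.0  # drive onto inhibitory population
    i_ie = 0.0  # hyperpolarizing drive onto excitatory population
    exc_spikes: list[tuple[float, int]] = []
    inh_spikes: list[tuple[float, int]] = []
    for s in range(n_steps):
        i_ei *= decay_inh
        i_ie *= decay_inh
        # excitatory neurons
        target = cfg.E_L + cfg.R_m * (I_in[:, s] - i_ie)
        v_e = target + (v_e - target) * decay_m
        v_e[ref_e > 0] = cfg.v_reset
        sp_e = (v_e >= theta) & (ref_e <= 0)
        if sp_e.sum() > 1:
            # discrete-time WTA: ties within one step resolve to the neuron
            # with the largest threshold margin (interneurons enforce the
            # lockout from the next step onward)
            margin = np.where(sp_e, v_e - theta, -np.inf)
            keep = int(margin.argmax())
            sp_e[:] = False
            sp_e[keep] = True
        v_e[sp_e] = cfg.v_reset
        ref_e = np.where(sp_e, refr_steps, np.maximum(ref_e - 1, 0))
        if sp_e.any():
            for e in np.nonzero(sp_e)[0]:
                exc_spikes.append((grid[s], int(e)))
            i_ei += cfg.w_exc_to_inh * int(sp_e.sum())
        # inhibitory interneurons (fixed threshold at the floor)
        target_i = cfg.E_L + cfg.R_m * i_ei
        v_i = target_i + (v_i - target_i) * decay_m
        v_i[ref_i > 0] = cfg.v_reset
        sp_i = (v_i >= cfg.theta_floor) & (ref_i <= 0)
        v_i[sp_i] = cfg.v_reset
        ref_i = np.where(sp_i, refr_steps, np.maximum(ref_i - 1, 0))
        if sp_i.any():
            for i in np.nonzero(sp_i)[0]:
                inh_spikes.append((grid[s], int(i)))
            i_ie += cfg.w_inh_to_exc * int(sp_i.sum())
    return exc_spikes, inh_spikes


def train(
    patterns: list[Trial],
    config: EiConfig = EiConfig(),
    presentations: int = 20,
    seed: int = 0,
) -> StructuralTrainResult:
    """Train the EI network on interleaved random presentations of patterns.

    Each pattern is presented ``presentations`` times in a random interleaved
    order.  Plasticity (STDP on w, decay, τ updates, respawn checks, threshold
    adaptation) triggers on the *first* spike of each excitatory neuron per
    presentation; membranes and synaptic currents reset between presentations
    (trial-separated simulation).  Afterwards a frozen evaluation pass
    presents each pattern once with all plasticity and adaptation off.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    n_e, n_in = cfg.n_exc, cfg.n_inputs
    w = np.clip(rng.normal(*cfg.spawn_w, size=(n_e, n_in)), 0.05, None) * cfg.w_max
    tau = np.clip(rng.normal(*cfg.spawn_tau, size=(n_e, n_in)), cfg.min_tau, None)
    theta = cfg.E_L + cfg.theta_init_above + rng.uniform(0.0, cfg.theta_init_spread, size=n_e)

    order = np.concatenate([rng.permutation(len(patterns)) for _ in range(presentations)])
    pats = [_pattern_ms(p) for p in patterns]

    raster: list[tuple[float, str, int]] = []
    winner_log: list[tuple[int, int | None]] = []
    theta_trace = np.zeros((len(order), n_e))
    t_offset = 0.0
    respawns = 0
    for pres_idx, pat_idx in enumerate(order):
        pattern = pats[pat_idx]
        exc_spikes, inh_spikes = _run_presentation(pattern, w, tau, theta, cfg)
        for k in range(n_in):
            raster.append((t_offset + pattern[k], "input", k))
        for t, e in exc_spikes:
            raster.append((t_offset + t, "exc", e))
        for t, i in inh_spikes:
            raster.append((t_offset + t, "inh", i))
        # plasticity at each neuron's first spike this presentation
        first_spike: dict[int, float] = {}
        for t, e in exc_spikes:
            first_spike.setdefault(e, t)
        winner_log.append((int(pat_idx), min(first_spike, key=first_spike.get) if first_spike else None))
        for e, t_post in first_spike.items():
            for k in range(n_in):
                w[e, k] += stdp_dw(pattern[k], t_post, cfg.stdp) * cfg.w_max
                tau[e, k] += stdp_dtau(t_post - pattern[k], cfg.stdp)
            w[e] = weight_decay(w[e], cfg.stdp)
            np.clip(w[e], 0.0, cfg.w_max, out=w[e])
            np.clip(tau[e], cfg.min_tau, 8.0, out=tau[e])
            theta[e] += cfg.theta_step
        if not first_spike:
            # nobody captured the pattern: lower every threshold so that
            # currently unreachable neurons re-enter the competition
            theta -= cfg.theta_miss_step
        # threshold relaxation toward the floor (homeostasis between events)
        theta = cfg.theta_floor + (theta - cfg.theta_floor) * cfg.theta_relax
        theta_trace[pres_idx] = theta
        # structural plasticity on a slow schedule
        if (pres_idx + 1) % cfg.respawn_every == 0:
            for e in range(n_e):
                w[e], tau[e], spawned = respawn_check(
                    w[e],
                    tau[e],
                    rng,
                    cfg.respawn_threshold * cfg.w_max,
                    spawn_w=cfg.spawn_w,
                    spawn_tau=cfg.spawn_tau,
                    min_tau=cfg.min_tau,
                )
                respawns += int(spawned)
        t_offset += pattern.max() + cfg.t_pad

    # frozen evaluation: synapses fixed.  The homeostatic threshold saws
    # around each neuron's separating level (up a step on each capture, down
    # on global misses), so a snapshot is a biased sample of it; instead the
    # thresholds run live through a few warm-up cycles and are then frozen
    # at their per-neuron cycle average — the settled separating level —
    # for one scored pass.
    theta_eval = theta.copy()
    theta_samples = []
    for _cycle in range(4):
        for pattern in pats:
            exc_spikes, _ = _run_presentation(pattern, w, tau, theta_eval, cfg)
            first_spike = {}
            for t, e in exc_spikes:
                first_spike.setdefault(e, t)
            for e in first_spike:
                theta_eval[e] += cfg.theta_step
            if not first_spike:
                theta_eval -= cfg.theta_miss_step
            theta_samples.append(theta_eval.copy())
    theta_bar = np.mean(theta_samples, axis=0)
    eval_responses = []
    for pattern in pats:
        exc_spikes, _ = _run_presentation(pattern, w, tau, theta_bar, cfg)
        eval_responses.append(sorted({e for _, e in exc_spikes}))

    return StructuralTrainResult(
        cfg, w, tau, theta, theta_trace, winner_log, raster, eval_responses, respawns
    )
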