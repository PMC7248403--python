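"""Unsupervised learning of synaptic conduction delays with WTA competition.

Eight input channels (the sensors) connect sparsely to a population of LIF
neurons; each connection carries a learnable conduction delay d_i.  A spike
emitted at time t_k on channel k arrives at s_i = t_k + d_i and injects an
exponential EPSC, giving the closed-form bi-exponential membrane response

    V_i(t) = E_L + R_m·I_inj·w_i·τ_syn/(τ_m − τ_syn)·(e^{−(t−s_i)/τ_m} − e^{−(t−s_i)/τ_syn})

(causal; one spike per synapse per pattern; membranes reset between
patterns).  The first neuron to cross threshold wins and only its delays
update,

    d_i ← d_i + η·g(t, s_i),    g(t, s_i) = R_m·I_inj·w_i/(τ_m − τ_syn)·(e^{−(t−s_i)/τ_m} − e^{−(t−s_i)/τ_syn})

evaluated at the winner's firing time t.  g is zero at coincidence and
EPSP-shaped in t − s_i, so spikes that arrived before the post-synaptic spike
are pulled later — toward the firing time — and repeated presentations
synchronize the winner's arrivals, specializing each neuron to one
spatio-temporal pattern.  The learning rate decays 10 % every 100 patterns.

``g`` as defined above is the update kernel the delay rule uses; the exact
partial derivative ∂V/∂s_i of the closed form carries additional 1/τ factors
and is available as ``gradient(..., form="exact")`` for verification against
finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from scorploc.arena import Dataset

__all__ = ["DelayNetConfig", "DelayTrainResult", "membrane", "gradient", "train", "sparsity_sweep"]


@dataclass(frozen=True)
class DelayNetConfig:
    """Network and plasticity constants (mV, MΩ, nA, ms)."""

    n_pre: int = 8
    n_post: int = 50
    n_connections: int = 4  # connections per post neuron (<= n_pre)
    delay_init_mu: float = 0.5  # ms
    delay_init_sigma: float = 0.3  # ms
    w0: float = 1.0  # per-synapse weight is w0 / n_connections
    E_L: float = -70.0
    v_thresh: float = -55.0
    tau_m: float = 2.0
    tau_syn: float = 0.5
    R_m: float = 1.0
    I_inj: float = 180.0
    eta0: float = 1.0
    eta_decay: float = 0.1  # fraction lost every eta_decay_every patterns
    eta_decay_every: int = 100
    resolution: float = 0.1  # ms, input quantization and integration step

    def __post_init__(self) -> None:
        if self.tau_m == self.tau_syn:
            raise ValueError("tau_m must differ from tau_syn (closed form degenerate)")
        if not 1 <= self.n_connections <= self.n_pre:
            raise ValueError("n_connections must be in [1, n_pre]")

    @property
    def w_syn(self) -> float:
        return self.w0 / self.n_connections


def membrane(
    arrivals_ms: np.ndarray,
    t_ms: np.ndarray | float,
    config: DelayNetConfig,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form membrane potential V(t) in mV for one neuron.

    ``arrivals_ms`` are the post-synaptic arrival times s_i (spike + delay) of
    the connected synapses; each synapse contributes zero before its arrival.
    """
    c = config
    s = np.atleast_1d(np.asarray(arrivals_ms, dtype=float))
    w = np.full(s.shape, c.w_syn) if weights is None else np.asarray(weights, dtype=float)
    t = np.atleast_1d(np.asarray(t_ms, dtype=float))
    u = np.clip(t[None, :] - s[:, None], 0.0, None)
    amp = c.R_m * c.I_inj * w * c.tau_syn / (c.tau_m - c.tau_syn)
    contrib = amp[:, None] * (np.exp(-u / c.tau_m) - np.exp(-u / c.tau_syn))
    contrib[t[None, :] < s[:, None]] = 0.0
    out = c.E_L + contrib.sum(axis=0)
    return out if np.ndim(t_ms) else float(out[0])


def gradient(
    arrivals_ms: np.ndarray,
    t_ms: float,
    config: DelayNetConfig,
    weights: np.ndarray | None = None,
    form: str = "update-kernel",
) -> np.ndarray:
    """Per-synapse delay-update kernel g(t, s_i), zero for s_i > t.

    ``form="update-kernel"`` (default) is the EPSP-shaped learning kernel used
    by :func:`train`; ``form="exact"`` is the true partial derivative
    ∂V/∂s_i of :func:`membrane`, which matches central finite differences.
    """
    c = config
    s = np.atleast_1d(np.asarray(arrivals_ms, dtype=float))
    w = np.full(s.shape, c.w_syn) if weights is None else np.asarray(weights, dtype=float)
    u = np.clip(float(t_ms) - s, 0.0, None)
    pref = c.R_m * c.I_inj * w / (c.tau_m - c.tau_syn)
    if form == "update-kernel":
        g = pref * (np.exp(-u / c.tau_m) - np.exp(-u / c.tau_syn))
    elif form == "exact":
        g = pref * ((c.tau_syn / c.tau_m) * np.exp(-u / c.tau_m) - np.exp(-u / c.tau_syn))
    else:
        raise ValueError(f"unknown form {form!r}")
    g[float(t_ms) < s] = 0.0
    return g


@dataclass
class DelayTrainResult:
    """Learned state plus bookkeeping for specialization analysis."""

    config: DelayNetConfig
    connectivity: np.ndarray  # (n_post, n_connections) pre indices
    delays_ms: np.ndarray  # (n_post, n_connections), all >= 0
    train_wins: np.ndarray  # (n_post, n_angles) winner counts during training
    eval_wins: np.ndarray  # (n_post, n_angles) winner counts, frozen pass
    angles_deg: np.ndarray  # angle label per column of the win matrices
    spread_history: list[float] = field(default_factory=list)

    def specialized(self, dominance: float = 0.8) -> np.ndarray:
        """Mask of neurons whose frozen-pass wins are >dominance one angle."""
        tot = self.eval_wins.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            share = self.eval_wins.max(axis=1) / tot
        return (tot > 0) & (share > dominance)

    def angle_coverage(self, dominance: float = 0.8) -> float:
        """Fraction of angles claimed by at least one specialized neuron."""
        mask = self.specialized(dominance)
        claimed = set(self.eval_wins[mask].argmax(axis=1).tolist())
        return len(claimed) / len(self.angles_deg)


def _pattern_times_ms(trial, resolution: float) -> np.ndarray:
    t = trial.spike_times.astype(float) / 1000.0  # µs -> ms
    t = np.round(t / resolution) * resolution
    return t - t.min()  # decoders use differences only


def _winner(V: np.ndarray, thresh: float) -> tuple[int, int] | None:
    """(neuron, time index) of the first threshold crossing; None if silent."""
    above = V >= thresh
    if not above.any():
        return None
    first = np.where(above.any(axis=1), above.argmax(axis=1), np.iinfo(np.int32).max)
    n = int(first.argmin())  # argmin breaks time ties by lowest index
    return n, int(first[n])


def train(
    dataset: Dataset, config: DelayNetConfig = DelayNetConfig(), seed: int = 0
) -> DelayTrainResult:
    """Train the delay-plasticity network on a dataset of first-spike patterns.

    Per presented pattern all membranes integrate from rest; the first neuron
    to reach threshold wins, its delays move by η·g evaluated at its firing
    time, and delays are clipped at zero.  Membrane state does not carry over
    between patterns.  Returns learned delays plus winner statistics from the
    training run and from a final frozen (η = 0) pass.

    Raises
    ------
    RuntimeError
        If no neuron ever fires (increase I_inj).
    """
    c = config
    rng = np.random.default_rng(seed)
    conn = np.array(
        [rng.choice(c.n_pre, size=c.n_connections, replace=False) for _ in range(c.n_post)]
    )
    delays = rng.normal(c.delay_init_mu, c.delay_init_sigma, size=(c.n_post, c.n_connections))
    delays = np.clip(delays, 0.0, None)

    angles = sorted({tr.position.angle_deg for tr in dataset.trials})
    angle_col = {a: i for i, a in enumerate(angles)}
    train_wins = np.zeros((c.n_post, len(angles)), dtype=int)
    spread_hist: list[float] = []
    any_fired = False

    def present(trial, delays, update: bool, eta: float, wins):
        nonlocal any_fired
        t_in = _pattern_times_ms(trial, c.resolution)
        arr = t_in[conn] + delays  # (n_post, n_conn)
        grid = np.arange(0.0, arr.max() + 5.0 * c.tau_m, c.resolution)
        u = np.clip(grid[None, None, :] - arr[:, :, None], 0.0, None)
        amp = c.R_m * c.I_inj * c.w_syn * c.tau_syn / (c.tau_m - c.tau_syn)
        contrib = amp * (np.exp(-u / c.tau_m) - np.exp(-u / c.tau_syn))
        contrib[grid[None, None, :] < arr[:, :, None]] = 0.0
        V = c.E_L + contrib.sum(axis=1)
        win = _winner(V, c.v_thresh)
        if win is None:
            return None
        any_fired = True
        n, ti = win
        wins[n, angle_col[trial.position.angle_deg]] += 1
        if update:
            # update kernel on the volt scale (membrane is in mV): at the
            # default eta = 1 this moves delays by ~0.01 ms per win
            g = gradient(arr[n], grid[ti], c) / 1000.0
            delays[n] = np.clip(delays[n] + eta * g, 0.0, None)
            assert np.all(delays[n] >= 0.0)
            spread_hist.append(float(np.std(t_in[conn[n]] + delays[n])))
        return n

    for i, tr in enumerate(dataset.trials):
        eta = c.eta0 * (1.0 - c.eta_decay) ** (i // c.eta_decay_every)
        present(tr, delays, update=True, eta=eta, wins=train_wins)
    if not any_fired:
        raise RuntimeError("no neuron ever fired; increase I_inj or lower v_thresh")

    eval_wins = np.zeros_like(train_wins)
    for tr in dataset.trials:
        present(tr, delays, update=False, eta=0.0, wins=eval_wins)

    return DelayTrainResult(
        c, conn, delays, train_wins, eval_wins, np.asarray(angles), spread_hist
    )


def sparsity_sweep(
    dataset: Dataset,
    config: DelayNetConfig = DelayNetConfig(),
    n_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8),
    n_trials: int = 35,
    seed: int = 0,
) -> dict[int, float]:
    """Mean angle coverage per connection count over random connectivities.

    For each N in ``n_values``, trains ``n_trials`` networks with independent
    random connectivity/delay draws and averages the fraction of angles
    represented by at least one specialized neuron.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for n in n_values:
        cfg = replace(config, n_connections=int(n))
        accs = [
            train(dataset, cfg, seed=int(rng.integers(2**31 - 1))).angle_coverage()
            for _ in range(n_trials)
        ]
        out[int(n)] = float(np.mean(accs))
    return out
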