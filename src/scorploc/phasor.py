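"""Complex-weight least-squares classifier on phase-encoded spikes.

Each trial's spike train (one first spike per sensor) is re-anchored to its
earliest spike t₀ and encoded as unit phasors

    s(k) = exp(jπ (t(k) − t₀) / T),         T = 2 r_max / c

so latency becomes phase; T bounds the geometric spread of arrivals so all
phases land in [0, π].  For every candidate position p a complex weight
vector ŵ_p is fitted by one-vs-rest least squares (targets 1 for trials at p,
0 elsewhere); the complex weights decode into a non-negative synaptic weight
and a signed delay:

    w_p(k) = |ŵ_p(k)|,      d_p(k) = (T/π) · arg ŵ_p(k)

Prediction scores a trial with ŷ_p = Σ_k ŵ_p(k) s(k); a matching trial sums
phase-aligned terms and lands near 1 on the unit circle.  The decision rule
is argmax Re(ŷ_p): a large-modulus but wrong-phase response should not win.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from scorploc.arena import Dataset, SensorArray, StimulusPosition, Trial
from scorploc.coincidence import fit_threshold

__all__ = ["PhasorEncodingParams", "PhasorModel", "encode", "fit", "predict", "window_T_us"]


def window_T_us(array: SensorArray, speed_m_per_s: float) -> float:
    """Phase-normalization window T = 2·r_max/c in µs."""
    return 2.0 * array.r_max * 1000.0 / speed_m_per_s


@dataclass(frozen=True)
class PhasorEncodingParams:
    """Phase window parameters; T is derived from the geometry and speed."""

    T_us: float
    speed_m_per_s: float

    @classmethod
    def for_array(cls, array: SensorArray, speed_m_per_s: float) -> "PhasorEncodingParams":
        return cls(window_T_us(array, speed_m_per_s), speed_m_per_s)


@dataclass
class PhasorModel:
    """Fitted complex weights per position plus decoded (w, d) and thresholds."""

    positions: list[StimulusPosition]
    weights: np.ndarray  # (n_positions, N_s) complex
    T_us: float
    thetas: np.ndarray  # per-position thresholds on |ŷ|
    rank_deficient: bool = False

    @property
    def decoded_weights(self) -> np.ndarray:
        """Real synaptic weights |ŵ| — non-negative, all synapses excitatory."""
        return np.abs(self.weights)

    @property
    def decoded_delays_us(self) -> np.ndarray:
        """Signed delays (T/π)·arg ŵ in µs, in [−T, T]."""
        return (self.T_us / np.pi) * np.angle(self.weights)

    @classmethod
    def reencode(cls, w: np.ndarray, d_us: np.ndarray, T_us: float) -> np.ndarray:
        """Inverse of the decode step: ŵ = w·exp(jπ d/T)."""
        return w * np.exp(1j * np.pi * d_us / T_us)


def encode(trial: Trial, T_us: float, window_slack_us: float = 2.0) -> np.ndarray:
    """Unit phasors for one trial; the earliest sensor maps to exactly 1+0j.

    Emits a warning when a spike falls outside [t₀, t₀+T]: its phase leaves
    [0, π], which means the configured speed or geometry does not cover the
    actual arrival spread.  On-axis stimuli reach the window bound exactly,
    so a small slack (ADC-tick scale) suppresses boundary false alarms.
    """
    t = trial.spike_times.astype(float)
    t0 = t.min()
    rel = t - t0
    if np.any(rel > T_us + window_slack_us):
        warnings.warn(
            f"trial {trial.trial_id}: spike {rel.max():.0f} µs after t0 exceeds "
            f"the phase window T = {T_us:.0f} µs; phase leaves [0, π]",
            stacklevel=2,
        )
    return np.exp(1j * np.pi * rel / T_us)


def fit(
    dataset: Dataset,
    grid: list[StimulusPosition] | None = None,
    speed_m_per_s: float | None = None,
) -> PhasorModel:
    """One-vs-rest complex least squares over all trials, one ŵ per position.

    The design matrix stacks every trial's phasor vector; for each position p
    the target is y_i = 1 for trials at p and 0 otherwise, minimizing the mean
    squared complex residual.  A rank-deficient design falls back to the
    minimum-norm pseudoinverse solution and is flagged on the model.
    Thresholds θ_p are fitted on |ŷ| with the empirical threshold sweep.
    """
    if grid is None:
        seen: dict[tuple[float, float], StimulusPosition] = {}
        for tr in dataset.trials:
            seen.setdefault(tr.position.label, tr.position)
        grid = list(seen.values())
    if speed_m_per_s is None:
        speed_m_per_s = float(dataset.meta.get("speed_m_per_s", 0)) or None
    if speed_m_per_s is None:
        from scorploc.coincidence import estimate_speed

        speed_m_per_s = estimate_speed(dataset)
    T = window_T_us(dataset.sensor_array, speed_m_per_s)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # aggregated below
        S = np.array([encode(tr, T) for tr in dataset.trials])  # (N_e, N_s) complex
    spreads = np.array([np.ptp(tr.spike_times) for tr in dataset.trials], dtype=float)
    n_outside = int(np.sum(spreads > T + 2.0))
    if n_outside:
        warnings.warn(
            f"{n_outside} trials have spikes outside the phase window "
            f"T = {T:.0f} µs (jitter or a misconfigured speed/geometry)",
            stacklevel=2,
        )
    labels = [tr.position.label for tr in dataset.trials]
    rank = np.linalg.matrix_rank(S)
    deficient = rank < min(S.shape)
    W = np.empty((len(grid), S.shape[1]), dtype=complex)
    thetas = np.empty(len(grid))
    for i, pos in enumerate(grid):
        y = np.array([1.0 if lab == pos.label else 0.0 for lab in labels])
        if not y.any():
            raise ValueError(f"no training example for position {pos.label}")
        W[i], *_ = np.linalg.lstsq(S, y.astype(complex), rcond=None)
        scores = np.abs(S @ W[i])
        thetas[i] = fit_threshold(scores, np.where(y > 0, 1, -1)).theta
    return PhasorModel(list(grid), W, T, thetas, deficient)


def predict(
    model: PhasorModel, trial: Trial, rule: str = "re"
) -> tuple[StimulusPosition, np.ndarray]:
    """Score a trial against every position; return (argmax position, scores ŷ).

    ``rule`` selects the decision statistic: ``"re"`` (default) uses Re(ŷ_p),
    ``"abs"`` uses |ŷ_p|.  Ties break to the lowest position index.
    """
    s = encode(trial, model.T_us)
    scores = model.weights @ s
    stat = scores.real if rule == "re" else np.abs(scores)
    return model.positions[int(np.argmax(stat))], scores
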