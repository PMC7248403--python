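"""Delayed-coincidence LIF detectors, one per candidate tap position.

Each detector neuron receives every sensor through a delayed synapse.  The
delays are chosen so that, for a tap at the detector's preferred position, all
eight spikes arrive at the neuron simultaneously:

    d_p(k) = d_p* − t_p(k),      d_p* = max_k t_p(k)

where t_p(k) is the geometric travel time from position p to sensor k at the
regressed wave speed.  The membrane potential is a sum of causal decaying
exponentials with unit weights,

    v_p(t) = Σ_k exp(−(t − t(k) − d_p(k))/τ) · Θ(t − t(k) − d_p(k))

whose maximum v_max reaches N_s exactly at perfect coincidence.  Firing
thresholds θ_p are fitted with an empirical sweep minimizing the count of
false negatives plus false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from scorploc.arena import Dataset, SensorArray, StimulusPosition, Trial

__all__ = [
    "CoincidenceDetector",
    "ThresholdFit",
    "estimate_speed",
    "build_detectors",
    "v_max",
    "fit_threshold",
    "fit_thresholds",
    "classify",
    "DEFAULT_TAU_US",
]

#: Membrane decay constant in µs.  Chosen well below the inter-sensor delay
#: spread (hundreds of µs to a few ms on the default geometry) so that only
#: genuinely coincident arrivals pile up.
DEFAULT_TAU_US = 100.0


@dataclass
class CoincidenceDetector:
    """One position detector: per-synapse delays plus (τ, θ)."""

    position: StimulusPosition
    delays_us: np.ndarray  # length N_s, all >= 0, min exactly 0
    tau_us: float = DEFAULT_TAU_US
    theta: float = 0.0  # firing threshold on v_max (dimensionless)


@dataclass
class ThresholdFit:
    """Result of the empirical threshold sweep.

    ``pairs`` is the (v_max, label) list sorted as swept; ``error`` is the
    achieved count of misclassifications at ``theta`` (rule: fire iff
    v_max >= theta).
    """

    pairs: list[tuple[float, int]]
    theta: float
    error: int


def estimate_speed(dataset: Dataset) -> float:
    """Wave speed (m/s) from distance-vs-delay regression with per-trial intercepts.

    Each (trial, sensor) pair contributes a point (delay, distance).  The tap
    onset is unknown to the decoder, so delays are only defined up to a
    per-trial constant; regressing with a per-trial intercept (equivalently,
    centering both variables within each trial) removes it, and any constant
    per-dataset sensor bias moves only the intercept, not the slope.
    """
    sxx = 0.0
    sxy = 0.0
    for tr in dataset.trials:
        d_m = (
            np.linalg.norm(
                dataset.sensor_array.positions - tr.position.cartesian, axis=1
            )
            / 1000.0
        )
        t_s = tr.spike_times.astype(float) * 1e-6
        x = t_s - t_s.mean()
        y = d_m - d_m.mean()
        sxx += float(x @ x)
        sxy += float(x @ y)
    if sxx == 0.0:
        raise ValueError("degenerate design: no within-trial delay spread")
    return sxy / sxx


def build_detectors(
    array: SensorArray,
    grid: list[StimulusPosition],
    speed_m_per_s: float,
    tau_us: float = DEFAULT_TAU_US,
) -> list[CoincidenceDetector]:
    """One detector per grid position with synchronizing delays.

    By construction ``t_p(k) + d_p(k)`` is the same for every k and the
    minimum delay is exactly 0.
    """
    if not speed_m_per_s > 0:
        raise ValueError("speed must be > 0")
    out = []
    for pos in grid:
        d_mm = np.linalg.norm(array.positions - pos.cartesian, axis=1)
        t_us = d_mm * 1000.0 / speed_m_per_s
        delays = t_us.max() - t_us
        out.append(CoincidenceDetector(pos, delays, tau_us))
    return out


def v_max(detector: CoincidenceDetector, trial: Trial) -> float:
    """Maximum membrane potential of the detector over the whole trial.

    v_p is piecewise decaying between arrivals, so its maximum occurs at one
    of the N_s delayed arrival times; evaluating there is exact.
    """
    a = trial.spike_times.astype(float) + detector.delays_us
    # v(a_j) = sum over k with a_k <= a_j of exp(-(a_j - a_k)/tau)
    diff = a[:, None] - a[None, :]  # diff[j, k] = a_j - a_k
    contrib = np.where(diff >= 0, np.exp(-np.clip(diff, 0, None) / detector.tau_us), 0.0)
    return float(contrib.sum(axis=1).max())


def fit_threshold(values: np.ndarray, labels: np.ndarray) -> ThresholdFit:
    """Empirical threshold minimizing false negatives + false positives.

    Sweeps the sorted-descending v_max values: starting from e = m_p (all
    positives missed) each value, when counted as firing, decrements e for a
    positive (label +1) and increments it for a negative (label −1); the θ
    with minimal e is kept.  Ties in v_max are swept negatives-first: every
    intermediate error the sweep reads then corresponds to a realizable
    threshold, so the result coincides with exhaustive minimization of the
    false-negative + false-positive count.  The firing rule is
    ``v_max >= theta``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (np.any(labels == 1) and np.any(labels == -1)):
        # degenerate single-class fits still get a sensible threshold
        if np.all(labels == 1):
            return ThresholdFit(
                sorted(zip(values, labels), key=lambda p: -p[0]), float(values.min()), 0
            )
        return ThresholdFit(
            sorted(zip(values, labels), key=lambda p: -p[0]), float(values.max()) + 1.0, 0
        )
    # descending by value; negatives before positives at equal value
    order = sorted(range(len(values)), key=lambda i: (-values[i], labels[i]))
    pairs = [(float(values[i]), int(labels[i])) for i in order]
    e = int(np.sum(labels == 1))
    best_e, best_theta = e, float(values.max()) + 1.0
    for val, lab in pairs:
        e -= lab
        if e < best_e:
            best_e, best_theta = e, val
    return ThresholdFit(pairs, best_theta, best_e)


def fit_thresholds(
    bank: list[CoincidenceDetector], dataset: Dataset
) -> list[ThresholdFit]:
    """Fit every detector's θ on the dataset (one-vs-rest labels), in place."""
    vm = np.array([[v_max(det, tr) for tr in dataset.trials] for det in bank])
    fits = []
    for i, det in enumerate(bank):
        labels = np.array(
            [1 if tr.position.label == det.position.label else -1 for tr in dataset.trials]
        )
        fit = fit_threshold(vm[i], labels)
        det.theta = fit.theta
        fits.append(fit)
    return fits


def classify(bank: list[CoincidenceDetector], trial: Trial) -> StimulusPosition:
    """Predicted position: argmax over detectors of v_max − θ (ties: lowest index)."""
    if not bank:
        raise ValueError("empty detector bank")
    scores = np.array([v_max(det, trial) - det.theta for det in bank])
    return bank[int(np.argmax(scores))].position
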