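"""Shared evaluation metrics: discrete angle/distance accuracy, circular
statistics of angular errors, and position-error CDFs for continuous solvers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from scorploc.arena import StimulusPosition

__all__ = [
    "EvalReport",
    "CircularStats",
    "angle_distance_accuracy",
    "circular_stats",
    "position_error_cdf",
    "wrap_angle_deg",
]


def wrap_angle_deg(err: np.ndarray | float) -> np.ndarray | float:
    """Wrap angular differences into (−180, 180]."""
    return -((-np.asarray(err, dtype=float) + 180.0) % 360.0 - 180.0)


@dataclass
class CircularStats:
    """Directional statistics of a sample of angular errors (degrees).

    ``mean_deg`` is the argument of the mean unit phasor; ``std_deg`` is
    √(−2 ln R̄).  For an antipodal sample R̄ ≈ 0 and the mean direction is
    undefined — check ``mean_defined``.
    """

    mean_deg: float
    std_deg: float
    r_bar: float

    @property
    def mean_defined(self) -> bool:
        return self.r_bar > 1e-9


@dataclass
class EvalReport:
    """Accuracy summary on the discrete 8-angle / 4-distance grid."""

    angle_accuracy: float  # percent
    distance_accuracy: float  # percent
    position_accuracy: float  # percent, both labels correct
    n_trials: int
    per_angle: dict[float, float] = field(default_factory=dict)  # angle -> % correct

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"angle {self.angle_accuracy:.1f} %  distance {self.distance_accuracy:.1f} %"
            f"  position {self.position_accuracy:.1f} %  (n={self.n_trials})"
        )


def angle_distance_accuracy(
    predictions: list[StimulusPosition],
    truths: list[StimulusPosition],
    grid: list[StimulusPosition] | None = None,
) -> EvalReport:
    """Exact-match accuracies on the discrete position grid.

    Position accuracy requires both the angle and the distance label to be
    correct, so it can never exceed either marginal accuracy.
    """
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    if not truths:
        raise ValueError("empty evaluation input")
    if grid is not None:
        allowed = {g.label for g in grid}
        for p in list(predictions) + list(truths):
            if p.label not in allowed:
                raise ValueError(f"label {p.label} outside the evaluation grid")
    ang = np.array([p.angle_deg == t.angle_deg for p, t in zip(predictions, truths)])
    dist = np.array([p.distance_mm == t.distance_mm for p, t in zip(predictions, truths)])
    per_angle = {}
    for a in sorted({t.angle_deg for t in truths}):
        m = np.array([t.angle_deg == a for t in truths])
        per_angle[a] = float(100.0 * (ang & dist)[m].mean())
    return EvalReport(
        angle_accuracy=float(100.0 * ang.mean()),
        distance_accuracy=float(100.0 * dist.mean()),
        position_accuracy=float(100.0 * (ang & dist).mean()),
        n_trials=len(truths),
        per_angle=per_angle,
    )


def circular_stats(errors_deg: np.ndarray) -> CircularStats:
    """Circular mean and standard deviation of angular errors in degrees."""
    e = np.radians(np.asarray(errors_deg, dtype=float))
    if e.size == 0:
        raise ValueError("empty sample")
    z = np.exp(1j * e).mean()
    r_bar = float(np.abs(z))
    mean = float(np.degrees(np.angle(z))) if r_bar > 1e-9 else 0.0
    std = float(np.degrees(sps.circstd(e)))
    return CircularStats(mean_deg=mean, std_deg=std, r_bar=r_bar)


def position_error_cdf(
    predicted_uv_mm: np.ndarray,
    truths: list[StimulusPosition],
    quantiles: tuple[float, ...] = (0.5, 0.8, 0.9, 0.95, 1.0),
) -> tuple[np.ndarray, dict[float, float]]:
    """Per-trial Euclidean position errors and their empirical quantiles (mm)."""
    uv = np.asarray(predicted_uv_mm, dtype=float).reshape(-1, 2)
    if uv.shape[0] != len(truths):
        raise ValueError("predictions and truths differ in length")
    true_uv = np.array([t.cartesian for t in truths])
    errors = np.linalg.norm(uv - true_uv, axis=1)
    table = {q: float(np.quantile(errors, q)) for q in quantiles}
    return errors, table
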