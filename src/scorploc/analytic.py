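"""Closed-form TDOA multilateration.

With sensors at (x_i, y_i) and arrival-time differences ΔT_1j = t_j − t_1
relative to a reference sensor, the unknown source (u, v), speed c, and
reference distance d satisfy, for every non-reference sensor j,

    (x1−xj)·u + (y1−yj)·v − ΔT_1j·(c·d) − (ΔT_1j²/2)·c² = (x1²+y1²−xj²−yj²)/2

which is linear in X = [u, v, c·d, c²] and solved with the normal-equation
pseudoinverse A⁺ = (AᵀA)⁻¹Aᵀ.  The speed is decoded as c = √X₄ and the
distance as d = X₃/c.  Internally everything runs in metres and seconds to
keep AᵀA well-scaled; interfaces stay in mm and µs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from scorploc.arena import Dataset, SensorArray, StimulusPosition, Trial, tdoa
from scorploc.wave_sim import WaveParams, first_spike_times

__all__ = [
    "AnalyticSolution",
    "DegenerateGeometryError",
    "build_system",
    "solve",
    "solve_trial",
    "solve_dataset",
    "conditioning_profile",
]


class DegenerateGeometryError(ValueError):
    """The TDOA system is rank-deficient (e.g. circular array or zero TDOAs)."""


@dataclass(frozen=True)
class AnalyticSolution:
    """Solution of one multilateration instance.

    ``valid`` is False when the decoded squared speed came out non-positive
    (a symptom of noise on an ill-conditioned instance); in that case ``c``
    and ``d`` are None rather than silently clamped.
    """

    u: float  # mm
    v: float  # mm
    c: float | None  # m/s
    d: float | None  # mm, source-to-reference-sensor distance
    condition_number: float
    raw_x: np.ndarray  # [u (m), v (m), c·d (m²/s), c² (m²/s²)]
    valid: bool

    @property
    def position(self) -> StimulusPosition:
        return StimulusPosition.from_cartesian(self.u, self.v)


def build_system(
    array: SensorArray, tdoa_us: np.ndarray, reference_sensor: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the (N_s−1)×4 linear system A·X = B in metres/seconds.

    ``tdoa_us`` follows the :func:`scorploc.arena.tdoa` convention
    (``t(reference) − t(j)``).
    """
    pos_m = array.positions / 1000.0
    n = array.n_sensors
    others = [j for j in range(n) if j != reference_sensor]
    x1, y1 = pos_m[reference_sensor]
    dT = -np.asarray(tdoa_us, dtype=float) * 1e-6  # ΔT_1j = t_j − t_1 in s
    A = np.empty((n - 1, 4))
    B = np.empty(n - 1)
    for row, j in enumerate(others):
        xj, yj = pos_m[j]
        A[row] = [x1 - xj, y1 - yj, -dT[row], -0.5 * dT[row] ** 2]
        B[row] = 0.5 * (x1**2 + y1**2 - xj**2 - yj**2)
    return A, B


def solve(
    array: SensorArray, tdoa_us: np.ndarray, reference_sensor: int = 0
) -> AnalyticSolution:
    """Least-squares solve of the TDOA system; decode position, speed, distance.

    Raises
    ------
    DegenerateGeometryError
        If rank(A) < 4 — the circular-array / all-zero-TDOA case.
    """
    A, B = build_system(array, tdoa_us, reference_sensor)
    if np.linalg.matrix_rank(A) < 4:
        raise DegenerateGeometryError(
            "TDOA system is rank-deficient; cannot localize (circular array "
            "or all time differences zero)"
        )
    X = np.linalg.solve(A.T @ A, A.T @ B)
    cond = float(np.linalg.cond(A))
    u_mm, v_mm = X[0] * 1000.0, X[1] * 1000.0
    if X[3] > 0:
        c = float(np.sqrt(X[3]))
        d_mm = float(X[2] / c * 1000.0)
        return AnalyticSolution(u_mm, v_mm, c, d_mm, cond, X, True)
    return AnalyticSolution(u_mm, v_mm, None, None, cond, X, False)


def solve_trial(
    array: SensorArray, trial: Trial, reference_sensor: int = 0
) -> AnalyticSolution:
    return solve(array, tdoa(trial, reference_sensor), reference_sensor)


def solve_dataset(dataset: Dataset, reference_sensor: int = 0) -> list[AnalyticSolution]:
    return [solve_trial(dataset.sensor_array, tr, reference_sensor) for tr in dataset.trials]


def conditioning_profile(
    array: SensorArray, grid: list[StimulusPosition], wave: WaveParams = WaveParams()
) -> np.ndarray:
    """Condition number of A for one noiseless trial per grid position.

    Maps which stimulus directions make the multilateration system
    ill-conditioned (condition numbers blow up without harming angle
    recovery — the error inflates along the range direction).
    """
    out = np.empty(len(grid))
    for i, pos in enumerate(grid):
        t = first_spike_times(array, pos, wave)
        dt = t[0] - t[1:]  # tdoa convention, unquantized
        A, _ = build_system(array, dt)
        out[i] = np.linalg.cond(A)
    return out
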