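"""Synthetic first-spike generator emulating a tap on a rigid plate.

A tap launches a wave that travels at a single speed ``c``; the noiseless
arrival time at sensor ``k`` is simply ``distance_k / c`` (the tap sits at the
centre of concentric circles).  On top of that the generator applies the three
distortions a real ADC-and-accelerometer pipeline introduces:

- i.i.d. Gaussian *jitter* per spike,
- a fixed per-sensor systematic *bias* (drawn once per dataset), dominating
  the error budget the way repeated recordings cluster in practice,
- *quantization* of timestamps to the ADC tick (default 1 µs).

An optional waveform path synthesizes a damped sinusoid per sensor and
extracts the first upward level crossing, mimicking level-crossing sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from scorploc.arena import Dataset, SensorArray, StimulusPosition, Trial

__all__ = [
    "NoiseModel",
    "WaveParams",
    "first_spike_times",
    "generate_dataset",
    "synth_waveform_and_threshold",
    "NO_SPIKE",
]

#: Default propagation speed in m/s: the value a distance-vs-delay regression
#: yields for a tapped wooden surface.  Plate surfaces generally fall in the
#: 50–300 m/s range.
DEFAULT_SPEED_M_PER_S = 126.0

#: Sentinel returned by the level-crossing path when the waveform never
#: reaches the threshold.
NO_SPIKE = math.inf


@dataclass(frozen=True)
class WaveParams:
    """Wavefront parameters.

    ``onset_policy`` is either ``"fixed-zero"`` (tap at t = 0) or
    ``"uniform-random"`` (tap at a uniform random time, used only to exercise
    decoder shift-invariance — decoders never see the onset).
    """

    speed: float = DEFAULT_SPEED_M_PER_S  # m/s
    onset_policy: str = "fixed-zero"

    def __post_init__(self) -> None:
        if not self.speed > 0:
            raise ValueError("wave speed must be > 0")
        if self.onset_policy not in ("fixed-zero", "uniform-random"):
            raise ValueError(f"unknown onset_policy {self.onset_policy!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Timestamp noise: Gaussian jitter, fixed per-sensor bias, quantization."""

    jitter_sigma: float = 20.0  # µs
    sensor_bias: np.ndarray | None = None  # µs, length N_s; None -> draw once
    bias_sigma: float = 50.0  # µs, used when sensor_bias is None
    quantization: float = 1.0  # µs

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if not self.quantization > 0:
            raise ValueError("quantization must be > 0")
        if self.sensor_bias is not None:
            object.__setattr__(
                self, "sensor_bias", np.asarray(self.sensor_bias, dtype=float)
            )

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(jitter_sigma=0.0, sensor_bias=np.zeros(0), bias_sigma=0.0)


def first_spike_times(
    array: SensorArray, position: StimulusPosition, wave: WaveParams
) -> np.ndarray:
    """Noiseless wavefront arrival times in µs (onset = 0, no quantization).

    ``time(k) = ||position - sensor_k|| / speed`` exactly.
    """
    d_mm = np.linalg.norm(array.positions - position.cartesian, axis=1)
    return d_mm * 1000.0 / wave.speed  # mm / (m/s) * 1000 = µs


def generate_dataset(
    array: SensorArray,
    grid: list[StimulusPosition],
    repetitions: int,
    wave: WaveParams = WaveParams(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> Dataset:
    """Generate ``len(grid) * repetitions`` trials, deterministic given seed.

    Per trial the emitted timestamp for sensor ``k`` is
    ``round_to_q(noiseless_k + onset + bias_k + N(0, jitter_sigma))`` where the
    bias vector is fixed for the whole dataset.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    rng = np.random.default_rng(seed)
    n = array.n_sensors
    if noise.sensor_bias is not None and noise.sensor_bias.size == n:
        bias = noise.sensor_bias
    elif noise.sensor_bias is not None and noise.sensor_bias.size == 0:
        bias = np.zeros(n)
    elif noise.sensor_bias is None:
        bias = rng.normal(0.0, noise.bias_sigma, size=n)
    else:
        raise ValueError("sensor_bias length must equal the sensor count")

    q = noise.quantization
    trials = []
    tid = 0
    for rep in range(repetitions):
        for pos in grid:
            clean = first_spike_times(array, pos, wave)
            if wave.onset_policy == "uniform-random":
                onset = float(rng.uniform(0.0, 1.0e6))
            else:
                onset = 0.0
            jitter = (
                rng.normal(0.0, noise.jitter_sigma, size=n)
                if noise.jitter_sigma > 0
                else np.zeros(n)
            )
            t = clean + onset + bias + jitter
            t_q = np.rint(t / q) * q
            onset_q = int(math.floor(min(onset, t_q.min())))
            trials.append(Trial(tid, pos, t_q.astype(np.int64), onset_q))
            tid += 1
    meta = {
        "speed_m_per_s": wave.speed,
        "jitter_sigma_us": noise.jitter_sigma,
        "bias_us": [float(b) for b in bias],
        "quantization_us": q,
        "seed": int(seed),
        "onset_policy": wave.onset_policy,
        "repetitions": int(repetitions),
    }
    return Dataset(array, trials, meta)


def _waveform(t_us: np.ndarray, arrival_us: float, carrier_hz: float, decay_us: float) -> np.ndarray:
    """Damped sinusoid starting at the arrival time (zero before)."""
    dt = t_us - arrival_us
    out = np.exp(-dt / decay_us) * np.sin(2.0 * np.pi * carrier_hz * dt * 1e-6)
    out[dt < 0] = 0.0
    return out


def synth_waveform_and_threshold(
    array: SensorArray,
    position: StimulusPosition,
    wave: WaveParams,
    level: float,
    amplitude: float = 1.0,
    carrier_hz: float = 1000.0,
    decay_us: float = 5000.0,
) -> np.ndarray:
    """First upward level crossings of a synthetic per-sensor waveform, in µs.

    Each sensor sees a damped sinusoid (unit carrier 1 kHz, 5 ms decay by
    default) starting at its wavefront arrival; the returned spike is the first
    time the signal rises through ``level``.  With amplitude >> level this
    equals the arrival time to within a quarter carrier period.  Sensors whose
    waveform never reaches the level get the :data:`NO_SPIKE` sentinel.
    """
    if not level > 0:
        raise ValueError("level must be > 0")
    arrivals = first_spike_times(array, position, wave)
    period_us = 1e6 / carrier_hz
    out = np.empty(array.n_sensors)
    for k, t0 in enumerate(arrivals):
        f = lambda t: amplitude * float(_waveform(np.array([t]), t0, carrier_hz, decay_us)[0]) - level
        # scan the first few carrier cycles on a fine grid for a sign change
        grid = t0 + np.linspace(0.0, 5 * period_us, 2001)[1:]
        vals = amplitude * _waveform(grid, t0, carrier_hz, decay_us) - level
        idx = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
        if vals[0] >= 0:
            out[k] = float(brentq(f, t0, grid[0])) if f(t0) < 0 else grid[0]
        elif len(idx):
            i = idx[0]
            out[k] = float(brentq(f, grid[i], grid[i + 1]))
        else:
            out[k] = NO_SPIKE
    return out
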