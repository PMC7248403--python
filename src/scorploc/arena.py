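"""Sensor-array geometry, core domain types, and the on-disk event format.

All other modules consume the types defined here.  Conventions used across
the package: positions are in millimetres with the array centroid at the
origin and angles measured counter-clockwise from +x; spike timestamps are
integers in microseconds (1 MHz ADC resolution); decoders may only use
*differences* of timestamps, never the stimulus onset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EventFileError",
    "SensorArray",
    "StimulusPosition",
    "Trial",
    "Dataset",
    "make_default_array",
    "default_grid",
    "tdoa",
    "write_events",
    "read_events",
]

#: Grid of the standard recording protocol: 8 angles every 45 degrees,
#: 4 distances in mm.
GRID_ANGLES_DEG = tuple(45.0 * k for k in range(8))
GRID_DISTANCES_MM = (200.0, 400.0, 600.0, 800.0)


class EventFileError(ValueError):
    """Raised when an event file or its sidecar is malformed."""


@dataclass(frozen=True)
class SensorArray:
    """Planar array of vibration sensors.

    Parameters
    ----------
    positions : (N_s, 2) array
        Sensor coordinates in mm, centroid at the origin.
    """

    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (N_s, 2) array")
        if pos.shape[0] < 5:
            # planar source localization is only well-defined with >= 5 sensors
            raise ValueError(f"need at least 5 sensors, got {pos.shape[0]}")
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() <= 0.0:
            raise ValueError("two sensors coincide")
        object.__setattr__(self, "positions", pos)

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    @property
    def r_max(self) -> float:
        """Maximum centroid-to-sensor distance in mm."""
        return float(np.linalg.norm(self.positions - self.centroid, axis=1).max())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SensorArray) and np.array_equal(
            self.positions, other.positions
        )

    def __hash__(self) -> int:
        return hash(self.positions.tobytes())


@dataclass(frozen=True)
class StimulusPosition:
    """Tap location in polar form relative to the array centroid."""

    angle_deg: float
    distance_mm: float

    def __post_init__(self) -> None:
        if not self.distance_mm > 0:
            raise ValueError("distance_mm must be > 0")
        object.__setattr__(self, "angle_deg", float(self.angle_deg) % 360.0)
        object.__setattr__(self, "distance_mm", float(self.distance_mm))

    @property
    def cartesian(self) -> np.ndarray:
        """(u, v) in mm; consistent with the polar form to < 1e-9 mm."""
        a = math.radians(self.angle_deg)
        return np.array(
            [self.distance_mm * math.cos(a), self.distance_mm * math.sin(a)]
        )

    @classmethod
    def from_cartesian(cls, u: float, v: float) -> "StimulusPosition":
        return cls(math.degrees(math.atan2(v, u)), math.hypot(u, v))

    @property
    def label(self) -> tuple[float, float]:
        return (self.angle_deg, self.distance_mm)


@dataclass(frozen=True)
class Trial:
    """One stimulus event: ground-truth position plus first-spike timestamps.

    ``onset`` is generator-private bookkeeping (the unknown tap time); decoders
    must never read it — they operate on timestamp differences only.
    """

    trial_id: int
    position: StimulusPosition
    spike_times: np.ndarray  # N_s integer microseconds, one first spike per sensor
    onset: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=np.int64)
        if t.ndim != 1:
            raise ValueError("spike_times must be a 1-D vector")
        if np.any(t < self.onset):
            raise ValueError("spike times precede stimulus onset")
        object.__setattr__(self, "spike_times", t)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Trial)
            and self.trial_id == other.trial_id
            and self.position == other.position
            and self.onset == other.onset
            and np.array_equal(self.spike_times, other.spike_times)
        )

    def __hash__(self) -> int:
        return hash((self.trial_id, self.position, self.onset))


@dataclass
class Dataset:
    """Ordered collection of trials plus the metadata that generated them."""

    sensor_array: SensorArray
    trials: list[Trial] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.sensor_array.n_sensors
        for tr in self.trials:
            if tr.spike_times.shape[0] != n:
                raise ValueError(
                    f"trial {tr.trial_id} has {tr.spike_times.shape[0]}/{n} sensors"
                )

    def __len__(self) -> int:
        return len(self.trials)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Dataset)
            and self.sensor_array == other.sensor_array
            and self.trials == other.trials
            and self.meta == other.meta
        )


def make_default_array() -> SensorArray:
    """Eight sensors at 45-degree parametric steps on a 150 mm x 100 mm ellipse.

    The ellipse is deliberately non-circular (a circular ring makes the TDOA
    system degenerate) and its 300 mm major axis reproduces a 1–1.5 ms
    opposite-sensor propagation time at surface speeds of 200–300 m/s.
    """
    a, b = 150.0, 100.0
    ang = np.radians(45.0 * np.arange(8))
    pos = np.column_stack([a * np.cos(ang), b * np.sin(ang)])
    # snap exact zeros so coordinates are bit-identical across platforms
    pos[np.abs(pos) < 1e-9] = 0.0
    return SensorArray(pos)


def default_grid() -> list[StimulusPosition]:
    """The 32-position stimulus grid: 8 angles x 4 distances."""
    return [
        StimulusPosition(ang, dist)
        for ang in GRID_ANGLES_DEG
        for dist in GRID_DISTANCES_MM
    ]


def tdoa(trial: Trial, reference_sensor: int = 0) -> np.ndarray:
    """Time differences of arrival relative to a reference sensor, in µs.

    Entry ``j`` (over non-reference sensors in index order) is
    ``t(reference) - t(j)``: positive when sensor ``j`` heard the wave *before*
    the reference.  Invariant under any constant shift of all spike times.
    """
    t = trial.spike_times.astype(float)
    ref = t[reference_sensor]
    mask = np.arange(t.shape[0]) != reference_sensor
    return ref - t[mask]


# ---------------------------------------------------------------------------
# Event-file format: CSV of first spikes + JSON sidecar with geometry/meta.
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["trial_id", "sensor_id", "time_us", "angle_deg", "distance_mm"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_events(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as an event CSV plus a JSON sidecar.

    The CSV holds one row per (trial, sensor) first spike; the sidecar holds
    sensor coordinates, generation metadata, and the generator-private onsets
    so that ``read_events`` is the exact inverse.
    """
    path = Path(path)
    rows = []
    for tr in dataset.trials:
        for k, t in enumerate(tr.spike_times):
            rows.append(
                (tr.trial_id, k, int(t), tr.position.angle_deg, tr.position.distance_mm)
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
    sidecar = {
        "sensor_positions_mm": dataset.sensor_array.positions.tolist(),
        "meta": dataset.meta,
        "onsets_us": {str(tr.trial_id): int(tr.onset) for tr in dataset.trials},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_events(path: str | Path) -> Dataset:
    """Read a dataset written by :func:`write_events`.

    Raises
    ------
    EventFileError
        On a malformed row (named by CSV line number), a trial with a wrong
        sensor count, or a missing sidecar.
    """
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise EventFileError(f"missing sidecar {side}")
    sidecar = json.loads(side.read_text())
    array = SensorArray(np.asarray(sidecar["sensor_positions_mm"], dtype=float))

    raw = pd.read_csv(path, dtype=str)
    if list(raw.columns) != _CSV_COLUMNS:
        raise EventFileError(f"unexpected columns {list(raw.columns)}")
    converted = {}
    for col, kind in zip(_CSV_COLUMNS, (int, int, int, float, float)):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise EventFileError(f"malformed value in column {col!r} at line {bad[0] + 2}")
        converted[col] = vals.astype(kind)
    df = pd.DataFrame(converted)

    onsets = {int(k): int(v) for k, v in sidecar.get("onsets_us", {}).items()}
    n = array.n_sensors
    trials = []
    for tid, grp in df.groupby("trial_id", sort=False):
        if len(grp) != n or sorted(grp["sensor_id"]) != list(range(n)):
            raise EventFileError(f"trial {tid} has {len(grp)}/{n} sensors")
        ang = grp["angle_deg"].iloc[0]
        dist = grp["distance_mm"].iloc[0]
        if grp["angle_deg"].nunique() != 1 or grp["distance_mm"].nunique() != 1:
            raise EventFileError(f"trial {tid} has inconsistent position labels")
        times = grp.sort_values("sensor_id")["time_us"].to_numpy(dtype=np.int64)
        trials.append(
            Trial(int(tid), StimulusPosition(ang, dist), times, onsets.get(int(tid), 0))
        )
    return Dataset(array, trials, sidecar.get("meta", {}))
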