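"""Three-ring temporal-difference-encoder (TDE) network for direction decoding.

The network turns the eight first-spike times into a one-hot direction code
without any training, exploiting only the wiring symmetry of the array:

- **TDE ring (8 neurons).**  TDE *k* has a *facilitating* synapse from sensor
  *k* and a *trigger* synapse from the diametrically opposite sensor *k+4*.
  A trigger spike injects current I_trig·f only while the facilitating trace
  f > 0, so the response is direction-selective (zero for the reversed spike
  order) and its magnitude decays with the time difference between the two
  sensors — largest information when the stimulus lies on the pair's axis.
- **Inverse-direction ring (8 neurons).**  Excited weakly by the adjacent
  TDEs and strongly (4×) by the opposite TDE; activity is minimal at the
  stimulus direction.
- **Direction ring (16 neurons).**  Inhibited by the inverse ring through a
  cosine-profile weight w_ij = w_peak·max(0, cos(θ_i − φ_j)) and driven by
  delayed uniform background excitation from the sensors, tuned so that,
  ideally, only the neuron at the stimulus direction escapes inhibition.
  Its spikes are the output "votes".

All neurons are leaky integrate-and-fire, integrated clock-driven with
exponential-Euler updates at dt = 0.1 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from scorploc.arena import Dataset, SensorArray, Trial

__all__ = ["TdeParams", "TdeNetwork", "build_network", "tde_response", "run_trial"]


@dataclass(frozen=True)
class TdeParams:
    """Neuron, synapse, and wiring constants (shared across the three rings).

    Voltages in mV, currents in nA, resistances in MΩ, times in ms.
    """

    # LIF
    E_L: float = -70.0
    R_m: float = 10.0
    tau_m: float = 10.0
    v_thresh: float = -50.0
    v_reset: float = -70.0
    refractory: float = 1.0
    # TDE synapse
    tau_syn_tde: float = 1.0
    w_fac: float = 1.0
    w_trig: float = 600.0  # fires the TDE for inter-sensor differences up to a few ms
    # ring synapses
    tau_syn_exc: float = 2.0
    tau_syn_inh: float = 20.0
    w_tde_weak: float = 5.0
    w_tde_strong: float = 20.0  # strong = 4x weak (opposite vs adjacent)
    w_peak_inh: float = 40.0
    # sensor -> direction background drive
    w_background: float = 20.0
    background_delay: float = 6.0  # ms; lets inhibition establish first
    refractory_direction: float = 10.0  # one vote per direction neuron per stimulus
    # simulation
    dt: float = 0.1
    t_pad: float = 20.0  # ms simulated past the last input spike


@dataclass
class TdeNetwork:
    """Wired network; stateless between trials (every run starts fresh)."""

    array: SensorArray
    params: TdeParams
    n_direction: int = 16
    #: inverse-ring nominal angles (deg): sensor index grid
    theta_deg: np.ndarray = field(init=False)
    #: direction-ring angles (deg)
    phi_deg: np.ndarray = field(init=False)
    #: (8 inverse, 16 direction) cosine inhibition weights
    w_inh: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.theta_deg = 45.0 * np.arange(8)
        self.phi_deg = (360.0 / self.n_direction) * np.arange(self.n_direction)
        diff = np.radians(self.theta_deg[:, None] - self.phi_deg[None, :])
        self.w_inh = self.params.w_peak_inh * np.maximum(0.0, np.cos(diff))


def build_network(array: SensorArray, params: TdeParams = TdeParams()) -> TdeNetwork:
    """Wire the three rings; requires 8 sensors in 4 diametrically opposite pairs."""
    if array.n_sensors != 8:
        raise ValueError("TDE ring wiring requires exactly 8 sensors")
    c = array.centroid
    rel = array.positions - c
    for k in range(4):
        if not np.allclose(rel[k], -rel[k + 4], atol=1e-6):
            raise ValueError("sensors are not arranged in opposite pairs")
    return TdeNetwork(array, params)


def _lif_step(V, I, fired_ref, p: TdeParams, decay_m):
    """Exponential-Euler LIF update; returns (V', spikes)."""
    target = p.E_L + p.R_m * I
    V_new = target + (V - target) * decay_m
    V_new = np.where(fired_ref > 0, p.v_reset, V_new)
    spikes = (V_new >= p.v_thresh) & (fired_ref <= 0)
    V_new = np.where(spikes, p.v_reset, V_new)
    return V_new, spikes


def run_trial(net: TdeNetwork, trial: Trial) -> dict[str, list[tuple[float, int]]]:
    """Simulate one trial; returns per-ring spike logs as (time_ms, neuron_id).

    Direction-ring spikes are the output votes.  A trial may yield no votes
    (miscalibrated background); callers should treat an empty ``"direction"``
    log as the empty-output flag.
    """
    p = net.params
    dt = p.dt
    t_us = trial.spike_times.astype(float)
    t_ms = (t_us - t_us.min()) / 1000.0  # decoders use differences only
    n_steps = int(np.ceil((t_ms.max() + p.t_pad) / dt)) + 1

    # input spike bins: sensor -> facilitation of TDE k, trigger of TDE k-4
    sensor_bin = np.floor(t_ms / dt).astype(int)
    bg_bin = np.floor((t_ms + p.background_delay) / dt).astype(int)

    decay_syn_tde = np.exp(-dt / p.tau_syn_tde)
    decay_exc = np.exp(-dt / p.tau_syn_exc)
    decay_inh = np.exp(-dt / p.tau_syn_inh)
    decay_m = np.exp(-dt / p.tau_m)
    refr_steps = int(round(p.refractory / dt))
    refr_steps_dir = int(round(p.refractory_direction / dt))

    f = np.zeros(8)
    i_trig = np.zeros(8)
    v_tde = np.full(8, p.E_L)
    ref_tde = np.zeros(8, dtype=int)

    i_inv = np.zeros(8)
    v_inv = np.full(8, p.E_L)
    ref_inv = np.zeros(8, dtype=int)

    i_dir_exc = np.zeros(net.n_direction)
    i_dir_inh = np.zeros(net.n_direction)
    v_dir = np.full(net.n_direction, p.E_L)
    ref_dir = np.zeros(net.n_direction, dtype=int)

    log: dict[str, list[tuple[float, int]]] = {"tde": [], "inverse": [], "direction": []}
    for step in range(n_steps):
        t_now = step * dt
        # decay synaptic state
        f *= decay_syn_tde
        i_trig *= decay_syn_tde
        i_inv *= decay_exc
        i_dir_exc *= decay_exc
        i_dir_inh *= decay_inh
        # deliver input spikes
        hits = sensor_bin == step
        if hits.any():
            ks = np.nonzero(hits)[0]
            f[ks] += p.w_fac  # facilitation of TDE k from sensor k
            # trigger of TDE k+4 from sensor k, gated at arrival: a trigger
            # spike with no facilitation trace is discarded outright, which
            # makes the reversed spike order produce exactly zero response
            trig_targets = (ks + 4) % 8
            gate = f[trig_targets] > 0
            i_trig[trig_targets[gate]] += p.w_trig
        bg_hits = int(np.sum(bg_bin == step))
        if bg_hits:
            i_dir_exc += p.w_background * bg_hits  # uniform background drive

        # TDE ring: gated current
        I_tde = np.where(f > 0, i_trig * f, 0.0)
        v_tde, sp_tde = _lif_step(v_tde, I_tde, ref_tde, p, decay_m)
        ref_tde = np.where(sp_tde, refr_steps, np.maximum(ref_tde - 1, 0))

        # inverse ring: weak from adjacent TDEs, strong from opposite
        if sp_tde.any():
            for k in np.nonzero(sp_tde)[0]:
                log["tde"].append((t_now, int(k)))
                i_inv[(k + 4) % 8] += p.w_tde_strong
                i_inv[(k + 1) % 8] += p.w_tde_weak
                i_inv[(k - 1) % 8] += p.w_tde_weak
        v_inv, sp_inv = _lif_step(v_inv, i_inv, ref_inv, p, decay_m)
        ref_inv = np.where(sp_inv, refr_steps, np.maximum(ref_inv - 1, 0))

        # direction ring: cosine inhibition + background excitation
        if sp_inv.any():
            for i in np.nonzero(sp_inv)[0]:
                log["inverse"].append((t_now, int(i)))
            i_dir_inh += net.w_inh[sp_inv].sum(axis=0)
        I_dir = i_dir_exc - i_dir_inh
        v_dir, sp_dir = _lif_step(v_dir, I_dir, ref_dir, p, decay_m)
        ref_dir = np.where(sp_dir, refr_steps_dir, np.maximum(ref_dir - 1, 0))
        for j in np.nonzero(sp_dir)[0]:
            log["direction"].append((t_now, int(j)))
    return log


def vote_angles_deg(net: TdeNetwork, log: dict) -> np.ndarray:
    """Direction-ring spike angles: each output spike votes for its neuron's angle."""
    return np.array([net.phi_deg[j] for _, j in log["direction"]])


def predict_angle_deg(net: TdeNetwork, log: dict, snap_deg: float = 45.0) -> float | None:
    """Per-trial angle estimate: the earliest vote, snapped to the grid.

    The direction neuron matching the stimulus escapes inhibition first, so
    the first output spike is the most reliable readout; later votes are
    neighbours firing as the inhibition decays.  Returns None for a trial
    with no votes.
    """
    if not log["direction"]:
        return None
    _, j = min(log["direction"])
    return float((np.round(net.phi_deg[j] / snap_deg) * snap_deg) % 360.0)


def tde_response(delta_t_ms: float, params: TdeParams = TdeParams()) -> float:
    """Peak injected current of a single TDE for a facilitation→trigger pair.

    ``delta_t_ms`` is trigger minus facilitation time; negative values (the
    reversed order) yield zero by the f-gating, which is the direction
    selectivity of the synapse pair.  For positive differences the peak decays
    monotonically with delta_t.
    """
    p = params
    dt = p.dt
    if delta_t_ms < 0:
        t_fac, t_trigg = -delta_t_ms, 0.0
    else:
        t_fac, t_trigg = 0.0, delta_t_ms
    n_steps = int((max(t_fac, t_trigg) + 10.0 * p.tau_syn_tde) / dt) + 1
    decay = np.exp(-dt / p.tau_syn_tde)
    f = 0.0
    i_trig = 0.0
    peak = 0.0
    fac_bin = int(np.floor(t_fac / dt))
    trig_bin = int(np.floor(t_trigg / dt))
    for step in range(n_steps):
        f *= decay
        i_trig *= decay
        if step == fac_bin:
            f += p.w_fac
        if step == trig_bin and f > 0:  # arrival-gated, see run_trial
            i_trig += p.w_trig
        if f > 0:
            peak = max(peak, i_trig * f)
    return peak


def calibrate_background(
    net: TdeNetwork,
    calibration: Dataset | list[Trial],
    weights: np.ndarray | None = None,
) -> TdeNetwork:
    """Grid-search the scalar background weight for a one-hot direction code.

    Scores each candidate by (fraction of trials with at least one vote)
    minus a penalty on mean extra votes per trial; deterministic given the
    calibration set.  Returns a re-parameterized network.
    """
    trials = calibration.trials if isinstance(calibration, Dataset) else calibration
    if weights is None:
        weights = np.array([8.0, 12.0, 16.0, 18.0, 20.0, 22.0, 25.0, 30.0, 40.0])
    best = None
    for w in weights:
        cand = TdeNetwork(net.array, replace(net.params, w_background=float(w)), net.n_direction)
        counts = []
        for tr in trials:
            counts.append(len(run_trial(cand, tr)["direction"]))
        counts = np.asarray(counts)
        score = float(np.mean(counts >= 1)) - 0.1 * float(np.mean(np.maximum(counts - 1, 0)))
        if best is None or score > best[0]:
            best = (score, cand)
    if best is None or best[0] <= 0.0:
        lo, hi = float(weights.min()), float(weights.max())
        raise ValueError(f"no background weight in [{lo}, {hi}] produces output spikes")
    return best[1]
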