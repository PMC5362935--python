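"""Synthetic voltage-clamp data with known ground truth.

Generates seeded sweeps that emulate the experimental protocols used to
measure intracellular chloride and resting chloride conductance in
dissociated neurons: zigzag voltage-ramp trains (+-1.6 V/s at a 20 Hz
cycle rate) around holding potentials near rest (-74 mV) and depolarised
levels (-14, -34 mV), agonist (GABA/glycine) applications gated by
first-order solution-exchange kinetics (tau ~ 50 ms), an ohmic or
exponential background leak, a resting chloride conductance reversing at
E_Cl, series-resistance voltage error, Gaussian recording noise, and
optional Poisson trains of miniature synaptic conductances.

The simulated pipette current at each sample is

    I = leak(V_m) + (g_Cl,rest + g_ag(t)) (V_m - E_Cl) [+ noise]

where the membrane voltage solves V_m = V_cmd - I(V_m) * Rs. When chloride
dynamics are coupled, [Cl-]_i (and hence E_Cl) is advanced from the
chloride-carried current via the channel-flux rule d[Cl] = I_Cl dt/(F v_equ).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import FARADAY
from .dynamics import CellState

__all__ = [
    "Segment",
    "AgonistWindow",
    "RampProtocol",
    "GroundTruthCell",
    "Sweep",
    "MiniTrain",
    "ConductanceTrace",
    "make_protocol",
    "simulate_sweep",
    "simulate_mini_train",
]


@dataclass
class Segment:
    """One constant-holding stretch of a protocol, optionally with a
    superimposed zigzag ramp train.

    The half-cycle ramp excursion is tied to the rate and cycle frequency:
    amplitude = rate / (2 * frequency), spanning symmetrically around the
    holding level (rate 1.6 V/s at 20 Hz -> 40 mV peak-to-peak).
    """

    holding_mV: float
    duration_s: float
    ramp_rate_V_per_s: float = 1.6
    cycle_hz: float = 20.0
    label: str = ""

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        if self.ramp_rate_V_per_s < 0 or self.cycle_hz <= 0:
            raise ValueError("ramp rate must be >= 0 and cycle frequency > 0")

    @property
    def amplitude_mV(self) -> float:
        """Peak-to-peak ramp excursion per half-cycle (mV)."""
        return self.ramp_rate_V_per_s / (2.0 * self.cycle_hz) * 1e3

    def waveform(self, t_rel: np.ndarray) -> np.ndarray:
        """Command voltage at times relative to segment start."""
        if self.ramp_rate_V_per_s == 0:
            return np.full(t_rel.shape, self.holding_mV)
        half = self.amplitude_mV / 2.0
        # triangle starting at the holding level, rising first
        phase = (t_rel * self.cycle_hz + 0.25) % 1.0
        tri = 4.0 * np.abs(phase - 0.5) - 1.0  # in [-1, 1], == 0 at t_rel = 0
        return self.holding_mV - half * tri


@dataclass
class AgonistWindow:
    """Agonist application interval (absolute protocol time).

    ``g_ag_nS`` is the target conductance; ``None`` means "use the cell's
    g_ag_max". The conductance relaxes toward its target with first-order
    solution-exchange kinetics (tau_exchange_s) on entering and leaving
    the window.
    """

    t_start_s: float
    t_end_s: float
    g_ag_nS: Optional[float] = None
    tau_exchange_s: float = 0.05
    label: str = ""

    def __post_init__(self):
        if self.t_end_s <= self.t_start_s:
            raise ValueError("agonist window must have positive duration")
        if self.tau_exchange_s <= 0:
            raise ValueError("exchange time constant must be positive")
        if self.g_ag_nS is not None and self.g_ag_nS < 0:
            raise ValueError("agonist conductance must be non-negative")


@dataclass
class RampProtocol:
    """Ordered segments plus agonist windows and the sampling interval."""

    segments: list
    agonist_windows: list = field(default_factory=list)
    sampling_interval_s: float = 1e-4
    name: str = ""

    def __post_init__(self):
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling interval must be positive")
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        total = self.total_duration_s
        for w in self.agonist_windows:
            if w.t_start_s < 0 or w.t_end_s > total:
                raise ValueError("agonist window outside protocol duration")

    @property
    def total_duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    def segment_bounds(self) -> list[tuple[float, float]]:
        """(start, end) absolute times of each segment."""
        edges = np.concatenate([[0.0], np.cumsum([s.duration_s for s in self.segments])])
        return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]

    def segment(self, label: str) -> tuple[Segment, float, float]:
        """Segment with the given label and its absolute (start, end)."""
        for seg, (a, b) in zip(self.segments, self.segment_bounds()):
            if seg.label == label:
                return seg, a, b
        raise KeyError(f"no segment labelled {label!r}")

    def window(self, label: str) -> AgonistWindow:
        for w in self.agonist_windows:
            if w.label == label:
                return w
        raise KeyError(f"no agonist window labelled {label!r}")

    def command_waveform(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (time, command voltage) arrays for the protocol."""
        n = int(round(self.total_duration_s / self.sampling_interval_s))
        t = np.arange(n) * self.sampling_interval_s
        v = np.empty(n)
        for seg, (a, b) in zip(self.segments, self.segment_bounds()):
            m = (t >= a) & (t < b)
            v[m] = seg.waveform(t[m] - a)
        return t, v


@dataclass
class GroundTruthCell:
    """Ground-truth membrane model behind a synthetic recording.

    The non-chloride background leak is either linear
    (slope_nS, reversal at leak_reversal_mV) or exponential
    I = a_pA + b_pA * exp(V/c_mV). The resting chloride conductance
    g_cl_rest_pS reverses at the Nernst E_Cl of the embedded CellState,
    as does any agonist-gated conductance. Default numbers mirror the
    in-blockers study conditions: total resting conductance ~0.48 nS of
    which 54 pS is chloride, Rs 20 MOhm, 5 pA current noise, baseline
    [Cl-]_i 9 mM.
    """

    leak_form: str = "linear"
    slope_nS: float = 0.426
    leak_reversal_mV: float = -74.0
    a_pA: float = 0.0
    b_pA: float = 0.0
    c_mV: float = 25.0
    g_cl_rest_pS: float = 54.0
    g_ag_max_nS: float = 7.5
    rs_Mohm: float = 20.0
    noise_sd_pA: float = 5.0
    cell: CellState = field(default_factory=lambda: CellState(cl_i_mM=9.0))

    def __post_init__(self):
        if self.leak_form not in ("linear", "exponential"):
            raise ValueError("leak_form must be 'linear' or 'exponential'")
        if self.leak_form == "exponential" and self.c_mV == 0:
            raise ValueError("exponential leak requires c_mV != 0")
        if self.rs_Mohm < 0 or self.noise_sd_pA < 0:
            raise ValueError("Rs and noise SD must be non-negative")
        if min(self.g_cl_rest_pS, self.g_ag_max_nS) < 0 or self.slope_nS < 0:
            raise ValueError("conductances must be non-negative")

    def leak_current_pA(self, v_mV):
        if self.leak_form == "linear":
            return self.slope_nS * (v_mV - self.leak_reversal_mV)
        return self.a_pA + self.b_pA * np.exp(v_mV / self.c_mV)

    def leak_slope_pA_per_mV(self, v_mV):
        if self.leak_form == "linear":
            return np.broadcast_to(self.slope_nS, np.shape(v_mV)).astype(float)
        return self.b_pA / self.c_mV * np.exp(v_mV / self.c_mV)

    def total_rest_conductance_nS(self, v_mV: float | None = None) -> float:
        """True resting slope conductance (leak + resting g_Cl) at v_mV."""
        v = self.leak_reversal_mV if v_mV is None else v_mV
        return float(self.leak_slope_pA_per_mV(v)) + self.g_cl_rest_pS * 1e-3


@dataclass
class Sweep:
    """One voltage-clamp record on a uniform time grid."""

    time_s: np.ndarray
    v_cmd_mV: np.ndarray
    i_pA: np.ndarray
    metadata: dict = field(default_factory=dict)
    truth_v_m_mV: Optional[np.ndarray] = None
    truth_cl_t_s: Optional[np.ndarray] = None
    truth_cl_mM: Optional[np.ndarray] = None

    def __post_init__(self):
        t, v, i = (np.asarray(a, dtype=float) for a in (self.time_s, self.v_cmd_mV, self.i_pA))
        if not (len(t) == len(v) == len(i)):
            raise ValueError("time, voltage and current must have equal length")
        dt = np.diff(t)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > np.median(dt)):
            raise ValueError("time grid must be strictly increasing and uniform")
        self.time_s, self.v_cmd_mV, self.i_pA = t, v, i

    @property
    def sampling_interval_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))


@dataclass
class MiniTrain:
    """Parameters of a Poisson train of miniature synaptic conductances.

    No study-specific event statistics are asserted; all values are
    user-set (defaults are exploratory placeholders).
    """

    rate_Hz: float = 2.0
    peak_g_nS: float = 0.5
    decay_tau_s: float = 0.020
    rise_tau_s: float = 0.001
    duration_s: float = 10.0

    def __post_init__(self):
        if min(self.rate_Hz, self.peak_g_nS, self.duration_s) < 0:
            raise ValueError("mini-train parameters must be non-negative")
        if not (0 < self.rise_tau_s < self.decay_tau_s):
            raise ValueError("require 0 < rise tau < decay tau")


@dataclass
class ConductanceTrace:
    time_s: np.ndarray
    g_nS: np.ndarray


# ---------------------------------------------------------------------------
# protocol templates

def _gcl_estimation_protocol(o: dict) -> RampProtocol:
    rate = o.pop("ramp_rate_V_per_s", 1.6)
    hz = o.pop("cycle_hz", 20.0)
    dt = o.pop("sampling_interval_s", 1e-4)
    rest_s = o.pop("rest_duration_s", 8.0)
    load_s = o.pop("loading_duration_s", 20.0)
    probe_s = o.pop("probe_duration_s", 2.0)
    tau_ex = o.pop("tau_exchange_s", 0.05)
    segs = [
        Segment(-74.0, rest_s, rate, hz, label="rest1"),
        Segment(-14.0, load_s + 4.0, rate, hz, label="load"),
        Segment(-74.0, rest_s, rate, hz, label="rest2"),
        Segment(-34.0, rest_s, rate, hz, label="probe2"),
    ]
    t_load = rest_s  # segment-2 start
    t_rest2 = t_load + load_s + 4.0
    windows = [
        AgonistWindow(4.0, 4.0 + probe_s, tau_exchange_s=tau_ex, label="probe1"),
        AgonistWindow(t_load + 2.0, t_load + 2.0 + load_s, tau_exchange_s=tau_ex,
                      label="loading"),
        AgonistWindow(t_rest2 + rest_s + 2.0, t_rest2 + rest_s + 2.0 + probe_s,
                      tau_exchange_s=tau_ex, label="probe2"),
    ]
    return RampProtocol(segs, windows, dt, name="gcl_estimation")


def _load_and_probe_protocol(o: dict) -> RampProtocol:
    rate = o.pop("ramp_rate_V_per_s", 1.6)
    hz = o.pop("cycle_hz", 20.0)
    dt = o.pop("sampling_interval_s", 1e-4)
    load_s = o.pop("loading_duration_s", 20.0)
    recovery_s = o.pop("recovery_duration_s", 60.0)
    recovery_holding = o.pop("recovery_holding_mV", -74.0)
    probe_times = o.pop("probe_times_s", None)
    probe_s = o.pop("probe_duration_s", 2.0)
    tau_ex = o.pop("tau_exchange_s", 0.05)
    segs = [
        Segment(-14.0, load_s + 4.0, rate, hz, label="load"),
        Segment(recovery_holding, recovery_s, rate, hz, label="recovery"),
    ]
    windows = [AgonistWindow(2.0, 2.0 + load_s, tau_exchange_s=tau_ex, label="loading")]
    t0 = load_s + 4.0
    if probe_times is None:
        probe_times = np.arange(5.0, recovery_s - probe_s, 15.0)
    for k, tp in enumerate(probe_times):
        windows.append(AgonistWindow(t0 + tp, t0 + tp + probe_s,
                                     tau_exchange_s=tau_ex, label=f"probe{k}"))
    return RampProtocol(segs, windows, dt, name="load_and_probe")


def _clc2_steps_protocol(o: dict) -> RampProtocol:
    dt = o.pop("sampling_interval_s", 1e-4)
    holding = o.pop("holding_mV", -34.0)
    levels = o.pop("step_levels_mV", list(np.arange(-114.0, -33.0, 10.0)))
    step_s = o.pop("step_duration_s", 1.0)
    inter_s = o.pop("inter_step_duration_s", 0.5)
    segs = []
    for lev in levels:
        segs.append(Segment(holding, inter_s, 0.0, 20.0, label="hold"))
        segs.append(Segment(float(lev), step_s, 0.0, 20.0, label=f"step_{lev:g}"))
    segs.append(Segment(holding, inter_s, 0.0, 20.0, label="hold"))
    proto = RampProtocol(segs, [], dt, name="clc2_steps")
    if min(levels) >= -65.0:
        raise ValueError("step family must reach below -65 mV for ClC-2 detection")
    return proto


_TEMPLATES = {
    "gcl_estimation": _gcl_estimation_protocol,
    "load_and_probe": _load_and_probe_protocol,
    "clc2_steps": _clc2_steps_protocol,
}


def make_protocol(template_name: str, overrides: dict | None = None) -> RampProtocol:
    """Build a named protocol template.

    Templates
    ---------
    gcl_estimation
        The resting-g_Cl sequence: ramps around -74 mV with a brief agonist
        probe (E_Cl1, g_T1, E_rev1), a 20 s agonist application at -14 mV
        loading the cell with chloride (E_Cl2a at its end), a second ramp
        train at -74 mV (g_T2, E_rev2), and a final probe around -34 mV
        (E_Cl2b).
    load_and_probe
        A 20 s load at -14 mV followed by a recovery phase with scheduled
        brief probe applications.
    clc2_steps
        A hyperpolarising voltage-step family reaching below -65 mV
        (ClC-2 detection template; no gating model attached).
    """
    if template_name not in _TEMPLATES:
        raise KeyError(f"unknown protocol template {template_name!r}")
    o = dict(overrides or {})
    proto = _TEMPLATES[template_name](o)
    if o:
        raise ValueError(f"unrecognised overrides: {sorted(o)}")
    return proto


# ---------------------------------------------------------------------------
# sweep simulation

def _agonist_gate_nS(protocol: RampProtocol, cell: GroundTruthCell,
                     t: np.ndarray) -> np.ndarray:
    """Summed agonist conductance with first-order exchange kinetics,
    evaluated piecewise-analytically per window."""
    g = np.zeros_like(t)
    for w in protocol.agonist_windows:
        target = cell.g_ag_max_nS if w.g_ag_nS is None else w.g_ag_nS
        if target == 0:
            continue
        tau = w.tau_exchange_s
        rising = (t >= w.t_start_s) & (t < w.t_end_s)
        g[rising] += target * (1.0 - np.exp(-(t[rising] - w.t_start_s) / tau))
        g_end = target * (1.0 - np.exp(-(w.t_end_s - w.t_start_s) / tau))
        after = t >= w.t_end_s
        g[after] += g_end * np.exp(-(t[after] - w.t_end_s) / tau)
    return g


def _solve_membrane_voltage(v_cmd, g_cl_nS, e_cl_mV, cell: GroundTruthCell,
                            tol_mV=1e-10, max_iter=60):
    """Newton solve of V = V_cmd - Rs * I(V) elementwise (voltages mV)."""
    rs = cell.rs_Mohm * 1e-3  # mV per pA
    v = np.array(v_cmd, dtype=float)
    if rs == 0:
        return v
    for _ in range(max_iter):
        i = cell.leak_current_pA(v) + g_cl_nS * (v - e_cl_mV)
        f = v - v_cmd + rs * i
        if np.max(np.abs(f)) < tol_mV:
            return v
        fp = 1.0 + rs * (cell.leak_slope_pA_per_mV(v) + g_cl_nS)
        v = v - f / fp
    raise RuntimeError("series-resistance voltage solve did not converge; "
                       "parameters are pathological")


def simulate_sweep(cell: GroundTruthCell, protocol: RampProtocol,
                   couple_cl_dynamics: bool = False, seed: int = 0) -> Sweep:
    """Simulate the recorded current for a cell under a protocol.

    With ``couple_cl_dynamics`` the intracellular chloride concentration is
    advanced every sample from the chloride-carried current (agonist plus
    resting g_Cl) via d[Cl] = I_Cl dt / (F v_equ); E_Cl is refreshed on a
    half-ramp-cycle grid (the drift per 25 ms chunk is far below a voltage
    bin). Identical configs and seeds give bit-identical sweeps.
    """
    rng = np.random.default_rng(seed)
    t, v_cmd = protocol.command_waveform()
    dt = protocol.sampling_interval_s
    g_ag = _agonist_gate_nS(protocol, cell, t)
    g_cl_rest_nS = cell.g_cl_rest_pS * 1e-3
    g_cl_tot = g_cl_rest_nS + g_ag
    state = cell.cell

    if not couple_cl_dynamics:
        e_cl = state.e_cl_mV()
        v_m = _solve_membrane_voltage(v_cmd, g_cl_tot, e_cl, cell)
        i_true = cell.leak_current_pA(v_m) + g_cl_tot * (v_m - e_cl)
        truth_cl_t = np.array([t[0], t[-1]])
        truth_cl = np.array([state.cl_i_mM, state.cl_i_mM])
    else:
        # chunked integration: E_Cl held within ~one half-cycle, chloride
        # advanced sample-by-sample inside each chunk
        chunk = max(1, int(round(1.0 / (2.0 * protocol.segments[0].cycle_hz) / dt)))
        n = len(t)
        v_m = np.empty(n)
        i_true = np.empty(n)
        cl = state.cl_i_mM
        flux_coef = dt / (FARADAY * state.v_equ_L) * 1e-12 * 1e3  # pA -> mM per sample
        from .constants import thermal_voltage_mV
        vt = thermal_voltage_mV(state.temperature_K)
        starts = range(0, n, chunk)
        truth_cl_t = np.empty(len(starts) + 1)
        truth_cl = np.empty(len(starts) + 1)
        for k, s0 in enumerate(starts):
            sl = slice(s0, min(s0 + chunk, n))
            truth_cl_t[k], truth_cl[k] = t[s0], cl
            e_cl = vt * np.log(cl / state.cl_o_mM)
            v_chunk = _solve_membrane_voltage(v_cmd[sl], g_cl_tot[sl], e_cl, cell)
            i_cl = g_cl_tot[sl] * (v_chunk - e_cl)
            v_m[sl] = v_chunk
            i_true[sl] = cell.leak_current_pA(v_chunk) + i_cl
            cl = cl + float(np.sum(i_cl)) * flux_coef
            if cl <= 0:
                raise RuntimeError("[Cl-]_i became non-positive during sweep")
        truth_cl_t[-1], truth_cl[-1] = t[-1] + dt, cl

    i_meas = i_true + (rng.normal(0.0, cell.noise_sd_pA, len(t))
                       if cell.noise_sd_pA > 0 else 0.0)
    meta = {
        "protocol": protocol.name,
        "seed": int(seed),
        "rs_Mohm": cell.rs_Mohm,
        "noise_sd_pA": cell.noise_sd_pA,
        "truth": {
            "g_cl_rest_pS": cell.g_cl_rest_pS,
            "g_ag_max_nS": cell.g_ag_max_nS,
            "leak_form": cell.leak_form,
            "total_rest_conductance_nS": cell.total_rest_conductance_nS(),
            "cl_i_start_mM": state.cl_i_mM,
            "cl_i_end_mM": float(truth_cl[-1]),
            "e_cl_start_mV": state.e_cl_mV(),
        },
    }
    return Sweep(t, v_cmd, i_meas, meta,
                 truth_v_m_mV=v_m, truth_cl_t_s=truth_cl_t, truth_cl_mM=truth_cl)


def simulate_mini_train(train: MiniTrain, seed: int = 0,
                        dt_s: float = 1e-3) -> ConductanceTrace:
    """Poisson train of difference-of-exponential conductance events.

    Each event contributes
    g(t) = A [exp(-(t-t_k)/tau_d) - exp(-(t-t_k)/tau_r)], normalised so the
    per-event peak equals ``peak_g_nS``. The trace is non-negative and
    reproducible for a fixed seed.
    """
    if train.duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(train.duration_s / dt_s))) * dt_s
    g = np.zeros_like(t)
    n_events = rng.poisson(train.rate_Hz * train.duration_s)
    if n_events == 0 or train.peak_g_nS == 0:
        return ConductanceTrace(t, g)
    event_times = np.sort(rng.uniform(0.0, train.duration_s, n_events))
    tr, td = train.rise_tau_s, train.decay_tau_s
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    amp = train.peak_g_nS / peak
    support = int(np.ceil(10 * td / dt_s))
    for t_k in event_times:
        i0 = int(np.floor(t_k / dt_s)) + 1
        i1 = min(i0 + support, len(t))
        if i0 >= len(t):
            continue
        g[i0:i1] += amp * (np.exp(-(t[i0:i1] - t_k) / td)
                           - np.exp(-(t[i0:i1] - t_k) / tr))
    return ConductanceTrace(t, np.maximum(g, 0.0))
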