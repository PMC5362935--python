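"""Single-compartment intracellular chloride dynamics.

The model tracks one state variable, [Cl-]_i, in a fixed "equivalent"
cytosolic volume v_equ under voltage clamp (V_m imposed). Two pathways
change [Cl-]_i per forward-Euler step of length dt:

* KCC2 cotransport, electroneutral and voltage independent, driven by the
  summed K+ and Cl- chemical potentials

      dmu_KCl = RT ( ln([Cl]_i/[Cl]_o) + ln([K]_i/[K]_o) )   [J/mol]
      d[Cl]_KCC2 = -dt * dmu_KCl * g_KCC2 / v_equ

  where g_KCC2 (mol^2 V^-1 C^-1 s^-1) is an apparent transport capacity.

* Conductive leak through chloride channels,

      I = g_Cl (V_m - E_Cl),    d[Cl]_cond = I dt / (F v_equ)

  with E_Cl from the Nernst relation. Outward current (V_m > E_Cl) loads
  the cell with chloride; at V_m < E_Cl chloride leaves.

All other ion pools ([K]_i, [K]_o, [Cl]_o) and the volume are held fixed.
KCC2-only dynamics relax to [Cl]_o [K]_o / [K]_i; conductive-only dynamics
relax E_Cl to V_m; the combined steady state lies strictly between.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .constants import FARADAY, R_GAS, thermal_voltage_mV
from .nernst import nernst_potential_mV

__all__ = [
    "CellState",
    "SimulationResult",
    "kcc2_driving_force",
    "kcc2_step",
    "conductive_step",
    "simulate",
    "steady_state",
    "equivalent_volume",
    "charge_for_load",
    "sphere_equivalent_volume",
]

MODES = ("kcc2", "conductive", "both")


@dataclass
class CellState:
    """State and parameters of the one-compartment chloride model.

    Defaults reflect the study conditions: recording-solution chloride
    146.4 mM, K+ 5/145 mM out/in, room temperature, a ~60 mM chloride
    load decaying toward rest, V_m clamped at -74 mV, resting chloride
    conductance 54 pS and the transporter factor matched to measured
    KCC2-mediated recovery.
    """

    cl_i_mM: float = 60.0
    cl_o_mM: float = 146.4
    k_i_mM: float = 145.0
    k_o_mM: float = 5.0
    v_m_mV: float = -74.0
    g_cl_pS: float = 54.0
    g_kcc2: float = 6.7e-21  # mol^2 V^-1 C^-1 s^-1
    v_equ_L: float = 5.0e-13
    temperature_K: float = 295.0

    def __post_init__(self):
        for name in ("cl_i_mM", "cl_o_mM", "k_i_mM", "k_o_mM"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.v_equ_L <= 0 or self.temperature_K <= 0:
            raise ValueError("v_equ_L and temperature_K must be positive")
        if self.g_cl_pS < 0 or self.g_kcc2 < 0:
            raise ValueError("conductances must be non-negative")

    def e_cl_mV(self) -> float:
        return nernst_potential_mV(self.cl_i_mM, self.cl_o_mM, self.temperature_K)

    def copy(self, **changes) -> "CellState":
        return replace(self, **changes)


@dataclass
class SimulationResult:
    """Forward-Euler trajectory with per-step flux bookkeeping."""

    time_s: np.ndarray
    cl_i_mM: np.ndarray
    e_cl_mV: np.ndarray
    d_kcc2_mM: np.ndarray        # per-step KCC2-mediated change
    d_conductive_mM: np.ndarray  # per-step channel-mediated change
    i_cl_pA: np.ndarray          # chloride current used in each step
    dt_s: float
    modes: str

    def final_cl_mM(self) -> float:
        return float(self.cl_i_mM[-1])


def kcc2_driving_force(state: CellState) -> float:
    """Summed K+/Cl- chemical potential driving KCC2 (J/mol)."""
    return R_GAS * state.temperature_K * (
        np.log(state.cl_i_mM / state.cl_o_mM) + np.log(state.k_i_mM / state.k_o_mM)
    )


def kcc2_step(state: CellState, dt_s: float) -> float:
    """KCC2-mediated change in [Cl-]_i over one step (mM)."""
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    dmu = kcc2_driving_force(state)
    return -dt_s * dmu * state.g_kcc2 / state.v_equ_L * 1e3  # mol/L -> mM


def conductive_step(state: CellState, dt_s: float,
                    v_m_mV: float | None = None,
                    g_cl_pS: float | None = None) -> float:
    """Channel-mediated change in [Cl-]_i over one step (mM).

    ``v_m_mV``/``g_cl_pS`` override the state's values (used for schedules).
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    v_m = state.v_m_mV if v_m_mV is None else v_m_mV
    g_cl = state.g_cl_pS if g_cl_pS is None else g_cl_pS
    i_A = g_cl * 1e-12 * (v_m - state.e_cl_mV()) * 1e-3  # S * V
    return i_A * dt_s / (FARADAY * state.v_equ_L) * 1e3


def _as_schedule(value, t: np.ndarray, default: float) -> np.ndarray:
    """Accept a scalar, per-step array, or callable(t) schedule."""
    if value is None:
        return np.full(t.shape, default)
    if callable(value):
        return np.asarray([float(value(ti)) for ti in t])
    value = np.asarray(value, dtype=float)
    if value.ndim == 0:
        return np.full(t.shape, float(value))
    if value.shape != t.shape:
        raise ValueError("schedule length must match number of steps")
    return value


def simulate(state: CellState, duration_s: float, dt_s: float = 0.05,
             modes: str = "both",
             v_m_mV: float | Sequence[float] | Callable | None = None,
             g_cl_pS: float | Sequence[float] | Callable | None = None,
             ) -> SimulationResult:
    """Integrate [Cl-]_i with fixed-step forward Euler.

    Parameters
    ----------
    modes : "kcc2", "conductive" or "both" — which flux terms are active.
    v_m_mV, g_cl_pS : optional schedules (scalar, per-step array evaluated at
        step-start times, or callable of time) overriding the state's values;
        used for loading phases or to add a mini-train conductance.
    """
    if modes not in MODES:
        raise ValueError(f"modes must be one of {MODES}")
    if duration_s <= 0 or dt_s <= 0:
        raise ValueError("duration and dt must be positive")

    n_steps = int(round(duration_s / dt_s))
    t_steps = np.arange(n_steps) * dt_s
    v_sched = _as_schedule(v_m_mV, t_steps, state.v_m_mV)
    g_sched = _as_schedule(g_cl_pS, t_steps, state.g_cl_pS)

    rt = R_GAS * state.temperature_K
    vt_mV = thermal_voltage_mV(state.temperature_K)
    ln_k = np.log(state.k_i_mM / state.k_o_mM)
    kcc2_on = modes in ("kcc2", "both")
    cond_on = modes in ("conductive", "both")
    kcc2_coef = state.g_kcc2 / state.v_equ_L * 1e3
    cond_coef = 1.0 / (FARADAY * state.v_equ_L) * 1e3

    cl = np.empty(n_steps + 1)
    e_cl = np.empty(n_steps + 1)
    d_k = np.zeros(n_steps)
    d_c = np.zeros(n_steps)
    i_cl = np.zeros(n_steps)
    cl[0] = state.cl_i_mM
    e_cl[0] = vt_mV * np.log(cl[0] / state.cl_o_mM)

    for n in range(n_steps):
        if kcc2_on:
            dmu = rt * (np.log(cl[n] / state.cl_o_mM) + ln_k)
            d_k[n] = -dt_s * dmu * kcc2_coef
        if cond_on:
            i_A = g_sched[n] * 1e-12 * (v_sched[n] - e_cl[n]) * 1e-3
            i_cl[n] = i_A * 1e12
            d_c[n] = i_A * dt_s * cond_coef
        cl[n + 1] = cl[n] + d_k[n] + d_c[n]
        if cl[n + 1] <= 0:
            raise RuntimeError(
                f"[Cl-]_i became non-positive at t={t_steps[n]:.3f} s; "
                "use a smaller dt or check parameters"
            )
        e_cl[n + 1] = vt_mV * np.log(cl[n + 1] / state.cl_o_mM)

    time = np.arange(n_steps + 1) * dt_s
    return SimulationResult(time, cl, e_cl, d_k, d_c, i_cl, dt_s, modes)


def steady_state(state: CellState, modes: str = "both") -> float:
    """Asymptotic [Cl-]_i (mM) for the given flux modes.

    kcc2-only and conductive-only have closed forms; the combined fixed
    point is bracketed by them and found by root finding on the summed
    fluxes.
    """
    if modes not in MODES:
        raise ValueError(f"modes must be one of {MODES}")
    cl_kcc2 = state.cl_o_mM * state.k_o_mM / state.k_i_mM
    vt = thermal_voltage_mV(state.temperature_K)
    cl_cond = state.cl_o_mM * np.exp(state.v_m_mV / vt)
    if modes == "kcc2":
        return cl_kcc2
    if modes == "conductive":
        return cl_cond
    if state.g_cl_pS == 0:
        return cl_kcc2
    if state.g_kcc2 == 0:
        return cl_cond

    def total_flux(cl_mM):
        s = state.copy(cl_i_mM=cl_mM)
        return kcc2_step(s, 1.0) + conductive_step(s, 1.0)

    lo, hi = sorted((cl_kcc2, cl_cond))
    if lo == hi:
        return lo
    return float(brentq(total_flux, lo, hi, xtol=1e-12))


def equivalent_volume(charge_C: float, delta_cl_mM: float) -> float:
    """Equivalent cytosolic volume v_equ = Q / (F * d[Cl]) in litres."""
    if delta_cl_mM == 0:
        raise ValueError("concentration change must be nonzero")
    return charge_C / (FARADAY * delta_cl_mM * 1e-3)


def charge_for_load(v_equ_L: float, delta_cl_mM: float) -> float:
    """Charge (C) that changes [Cl-]_i by delta in volume v_equ; inverse
    of :func:`equivalent_volume`."""
    return v_equ_L * FARADAY * delta_cl_mM * 1e-3


def sphere_equivalent_volume(radius_um: float = 6.2, fraction: float = 0.5) -> float:
    """Equivalent volume as a fraction of a spherical cell's volume (litres)."""
    if radius_um <= 0 or not (0 < fraction <= 1):
        raise ValueError("radius must be positive and fraction in (0, 1]")
    r_m = radius_um * 1e-6
    return fraction * (4.0 / 3.0) * np.pi * r_m**3 * 1e3  # m^3 -> L
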