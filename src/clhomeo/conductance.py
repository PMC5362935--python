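"""Resting chloride conductance from reversal-potential shifts.

If the membrane's resting reversal potential obeys the conductance form of
the Goldman-Hodgkin-Katz relation and only E_Cl changes between two
measurements (total conductance g_T and the Na+/K+ equilibria constant),
then the relative resting chloride conductance follows from the shift in
resting reversal potential alone:

    g_Cl / g_T = (E_rev2 - E_rev1) / (E_Cl2 - E_Cl1)

The protocol that realises the two conditions: measure (g_T1, E_rev1,
E_Cl1) with ramps near rest, load the cell with chloride by a 20 s agonist
application at a depolarised holding, then re-measure (g_T2, E_rev2) near
rest and E_Cl twice (right after loading and later at -34 mV) so E_Cl at
the E_rev2 time can be linearly interpolated. QC rejects cells whose g_T
changed by >= 30%. Because the measurement cocktail (TEA, Cd2+, TTX, KCC2
blocker) lowers g_T, the ratio measured in blockers is rescaled to a
blocker-free basis by the measured attenuation factor (default 0.54).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ivramp import (build_iv_from_ramp, correct_series_resistance,
                     estimate_reversal_potential, estimate_slope_conductance,
                     fit_leak_model, subtract_leak)
from .nernst import NernstContext
from .synthetic import RampProtocol, Sweep

__all__ = [
    "ConductanceEstimate",
    "GclAnalysisConfig",
    "relative_gcl",
    "interpolate_ecl",
    "qc_total_conductance",
    "blocker_correction",
    "blocker_free_total_conductance",
    "attenuation_ratio",
    "absolute_gcl",
    "run_gcl_protocol",
]


def relative_gcl(e_rev1_mV: float, e_rev2_mV: float,
                 e_cl1_mV: float, e_cl2_mV: float) -> float:
    """Relative resting chloride conductance dErev/dECl (dimensionless)."""
    d_ecl = e_cl2_mV - e_cl1_mV
    if d_ecl == 0:
        raise ZeroDivisionError("E_Cl shift is zero; estimator undefined")
    return (e_rev2_mV - e_rev1_mV) / d_ecl


def interpolate_ecl(e_cl_a_mV: float, t_a_s: float,
                    e_cl_b_mV: float, t_b_s: float, t_target_s: float) -> float:
    """Linear-in-time interpolation of E_Cl between two measurements."""
    if t_a_s == t_b_s:
        raise ValueError("measurement times must differ")
    if not (min(t_a_s, t_b_s) <= t_target_s <= max(t_a_s, t_b_s)):
        warnings.warn("target time outside measurement interval (extrapolating)")
    frac = (t_target_s - t_a_s) / (t_b_s - t_a_s)
    return e_cl_a_mV + frac * (e_cl_b_mV - e_cl_a_mV)


def qc_total_conductance(g_t1_nS: float, g_t2_nS: float,
                         threshold: float = 0.30) -> tuple[bool, float]:
    """Constant-g_T check: fail iff |g_T2 - g_T1| / g_T1 >= threshold."""
    if g_t1_nS <= 0 or g_t2_nS <= 0:
        raise ValueError("conductances must be positive")
    change = abs(g_t2_nS - g_t1_nS) / g_t1_nS
    return change < threshold, g_t2_nS / g_t1_nS


def blocker_correction(rel_gcl_in_blockers: float, factor: float = 0.54) -> float:
    """Re-express a relative g_Cl measured in blockers on a blocker-free basis.

    g_Cl itself is unchanged by the blockers while g_T without blockers is
    larger by 1/factor, so the blocker-free ratio is the in-blockers ratio
    times the attenuation factor.
    """
    if not (0 < factor <= 1):
        raise ValueError("attenuation factor must be in (0, 1]")
    return rel_gcl_in_blockers * factor


def blocker_free_total_conductance(g_t_in_blockers_nS: float,
                                   factor: float = 0.54) -> float:
    """Back-calculate the blocker-free total conductance (nS)."""
    if not (0 < factor <= 1):
        raise ValueError("attenuation factor must be in (0, 1]")
    return g_t_in_blockers_nS / factor


def attenuation_ratio(rel_gcl_treated: float, rel_gcl_control: float) -> float:
    """Ratio of a treated-condition relative g_Cl to its control value."""
    if rel_gcl_control == 0:
        raise ZeroDivisionError("control relative g_Cl is zero")
    return rel_gcl_treated / rel_gcl_control


def absolute_gcl(rel_gcl: float, g_t_nS: float) -> float:
    """Absolute chloride conductance (pS) from a ratio and total conductance."""
    if rel_gcl < 0 or g_t_nS <= 0:
        raise ValueError("inputs must be positive")
    return rel_gcl * g_t_nS * 1e3


@dataclass
class GclAnalysisConfig:
    """Numerical choices of the g_Cl protocol analysis."""

    bin_mV: float = 1.0
    blank_ms: float = 2.0
    leak_form: str = "exponential"
    slope_half_width_mV: float = 15.0
    settle_s: float = 0.3            # skipped after each holding change
    agonist_rise_skip_s: float = 0.3  # skipped after agonist onset (~6 tau)
    agonist_tail_s: float = 1.0       # averaging window at end of loading
    washout_s: float = 0.5            # skipped after agonist offset
    blocker_factor: float = 0.54
    gt_change_threshold: float = 0.30


@dataclass
class ConductanceEstimate:
    """Paired pre/post-load measurements and the derived g_Cl."""

    e_rev1_mV: float
    e_rev2_mV: float
    e_cl1_mV: float
    e_cl2a_mV: float
    t_ecl2a_s: float
    e_cl2b_mV: float
    t_ecl2b_s: float
    e_cl2_mV: float           # interpolated to the g_T2 / E_rev2 time
    t_gt2_s: float
    g_t1_nS: float
    g_t2_nS: float
    rel_gcl_in_blockers: float
    blocker_factor: float
    rel_gcl_blocker_free: float
    abs_gcl_pS: float
    cl1_mM: Optional[float] = None
    cl2_mM: Optional[float] = None
    qc_pass: bool = True
    qc_flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["qc_flags"] = list(self.qc_flags)
        return d


def _phase_ecl(sweep, v_corr, leak_iv, intervals, cfg, label) -> float:
    """E_Cl from an agonist interval: leak model subtracted, zero crossing."""
    leak = fit_leak_model(leak_iv, form=cfg.leak_form)
    iv_ag = build_iv_from_ramp(sweep, v_corr, intervals=intervals,
                               bin_mV=cfg.bin_mV, blank_ms=cfg.blank_ms)
    diff = subtract_leak(iv_ag, leak)
    try:
        return estimate_reversal_potential(diff)
    except ValueError as err:
        raise ValueError(f"no E_Cl reversal in phase {label!r}: {err}") from err


def run_gcl_protocol(sweep: Sweep, protocol: RampProtocol, rs_Mohm: float,
                     config: GclAnalysisConfig | None = None,
                     nernst_ctx: NernstContext | None = None,
                     ) -> ConductanceEstimate:
    """Full resting-g_Cl analysis of a g_Cl-estimation protocol sweep.

    Expects a protocol with segments labelled rest1/load/rest2/probe2 and
    agonist windows probe1/loading/probe2 (as built by
    ``make_protocol("gcl_estimation")``). Returns the estimate with QC
    flags; a QC failure is flagged, never silently clipped.
    """
    cfg = config or GclAnalysisConfig()
    v_corr = correct_series_resistance(sweep, rs_Mohm)

    def leak_iv(intervals):
        return build_iv_from_ramp(sweep, v_corr, intervals=intervals,
                                  bin_mV=cfg.bin_mV, blank_ms=cfg.blank_ms)

    # --- phase 1: rest (-74 mV), leak ramps flank the E_Cl1 probe
    seg1, a1, b1 = protocol.segment("rest1")
    w1 = protocol.window("probe1")
    leak1_intervals = [(a1 + cfg.settle_s, w1.t_start_s - 0.1),
                       (w1.t_end_s + cfg.washout_s, b1 - 0.05)]
    iv_leak1 = leak_iv(leak1_intervals)
    e_rev1 = estimate_reversal_potential(iv_leak1)
    g_t1 = estimate_slope_conductance(iv_leak1, center_mV=seg1.holding_mV,
                                      half_width_mV=cfg.slope_half_width_mV)
    e_cl1 = _phase_ecl(sweep, v_corr, iv_leak1,
                       [(w1.t_start_s + cfg.agonist_rise_skip_s, w1.t_end_s)],
                       cfg, "probe1")

    # --- phase 2: loading (-14 mV); E_Cl2a from the end of the application
    seg2, a2, b2 = protocol.segment("load")
    wload = protocol.window("loading")
    iv_leak2 = leak_iv([(a2 + cfg.settle_s, wload.t_start_s - 0.1)])
    e_cl2a = _phase_ecl(sweep, v_corr, iv_leak2,
                        [(wload.t_end_s - cfg.agonist_tail_s, wload.t_end_s)],
                        cfg, "loading")
    t_ecl2a = wload.t_end_s - cfg.agonist_tail_s / 2.0

    # --- phase 3: second rest (-74 mV): g_T2, E_rev2
    seg3, a3, b3 = protocol.segment("rest2")
    iv_leak3 = leak_iv([(a3 + cfg.settle_s, b3 - 0.05)])
    e_rev2 = estimate_reversal_potential(iv_leak3)
    g_t2 = estimate_slope_conductance(iv_leak3, center_mV=seg3.holding_mV,
                                      half_width_mV=cfg.slope_half_width_mV)
    t_gt2 = (a3 + cfg.settle_s + b3 - 0.05) / 2.0

    # --- phase 4: -34 mV probe: E_Cl2b
    seg4, a4, b4 = protocol.segment("probe2")
    w4 = protocol.window("probe2")
    iv_leak4 = leak_iv([(a4 + cfg.settle_s, w4.t_start_s - 0.1)])
    e_cl2b = _phase_ecl(sweep, v_corr, iv_leak4,
                        [(w4.t_start_s + cfg.agonist_rise_skip_s, w4.t_end_s)],
                        cfg, "probe2")
    t_ecl2b = (w4.t_start_s + cfg.agonist_rise_skip_s + w4.t_end_s) / 2.0

    # --- combine
    e_cl2 = interpolate_ecl(e_cl2a, t_ecl2a, e_cl2b, t_ecl2b, t_gt2)
    qc_pass, _ratio = qc_total_conductance(g_t1, g_t2,
                                           threshold=cfg.gt_change_threshold)
    rel = relative_gcl(e_rev1, e_rev2, e_cl1, e_cl2)
    rel_free = blocker_correction(rel, cfg.blocker_factor)
    # negative estimates (possible under noise) propagate unclipped
    abs_ps = rel * 0.5 * (g_t1 + g_t2) * 1e3

    flags = []
    if not qc_pass:
        flags.append(f"g_T changed by {abs(g_t2 - g_t1) / g_t1:.0%} "
                     f"(limit {cfg.gt_change_threshold:.0%})")
    if not (0.0 <= rel <= 1.0):
        flags.append(f"relative g_Cl {rel:.3f} outside [0, 1] (reported as-is)")

    cl1 = cl2 = None
    if nernst_ctx is not None:
        cl1 = nernst_ctx.chloride(e_cl1)
        cl2 = nernst_ctx.chloride(e_cl2)

    return ConductanceEstimate(
        e_rev1_mV=e_rev1, e_rev2_mV=e_rev2, e_cl1_mV=e_cl1,
        e_cl2a_mV=e_cl2a, t_ecl2a_s=t_ecl2a,
        e_cl2b_mV=e_cl2b, t_ecl2b_s=t_ecl2b,
        e_cl2_mV=e_cl2, t_gt2_s=t_gt2,
        g_t1_nS=g_t1, g_t2_nS=g_t2,
        rel_gcl_in_blockers=rel, blocker_factor=cfg.blocker_factor,
        rel_gcl_blocker_free=rel_free, abs_gcl_pS=abs_ps,
        cl1_mM=cl1, cl2_mM=cl2,
        qc_pass=qc_pass, qc_flags=flags,
    )
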