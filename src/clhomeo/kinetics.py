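"""Loading/recovery kinetics of [Cl-]_i time courses.

Sparse probe measurements of [Cl-]_i (one per agonist probe ramp train)
are summarised by single-exponential fits

    y(t) = asymptote + amplitude * exp(-(t - t0)/tau)

with free asymptote, plus normalised recovery fractions and probe-time
interpolation. Recoveries in real cells are sometimes bi-exponential or
near-linear; the single-exponential is the common-denominator summary,
and a double-exponential variant is available for diagnostics only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np

from .constants import FARADAY

__all__ = [
    "TimeSeriesCl",
    "ExpFit",
    "fit_single_exponential",
    "fit_double_exponential",
    "recovery_fraction",
    "interpolate_at",
    "probe_perturbation_bound",
]


@dataclass
class TimeSeriesCl:
    """Probe-time series of intracellular chloride estimates."""

    t_s: np.ndarray
    cl_mM: np.ndarray
    baseline_mM: Optional[float] = None
    peak_mM: Optional[float] = None
    phase: Optional[np.ndarray] = None  # labels "loading"/"recovery" per point

    def __post_init__(self):
        t = np.asarray(self.t_s, dtype=float)
        y = np.asarray(self.cl_mM, dtype=float)
        if len(t) != len(y):
            raise ValueError("times and concentrations must have equal length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("probe times must be strictly increasing")
        self.t_s, self.cl_mM = t, y
        if self.peak_mM is None:
            self.peak_mM = float(y.max()) if len(y) else None

    def select_phase(self, phase: str) -> "TimeSeriesCl":
        if self.phase is None:
            return self
        m = np.asarray(self.phase) == phase
        return TimeSeriesCl(self.t_s[m], self.cl_mM[m],
                            baseline_mM=self.baseline_mM, peak_mM=self.peak_mM)


@dataclass
class ExpFit:
    amplitude_mM: float
    tau_s: float
    asymptote_mM: float
    t0_s: float
    rmse_mM: float
    converged: bool
    flags: list = field(default_factory=list)

    def predict(self, t_s):
        t = np.asarray(t_s, dtype=float)
        return self.asymptote_mM + self.amplitude_mM * np.exp(-(t - self.t0_s) / self.tau_s)


def _exp_initial_guess(t, y):
    c0 = float(y[-1])
    a0 = float(y[0] - c0)
    # log-linear pre-fit on the baseline-subtracted branch
    resid = (y - c0) / a0 if a0 != 0 else None
    if resid is not None:
        m = resid > 1e-3
        if np.count_nonzero(m) >= 3:
            slope = np.polyfit(t[m] - t[0], np.log(resid[m]), 1)[0]
            if slope < 0:
                return a0, -1.0 / slope, c0
    span = float(t[-1] - t[0])
    return a0, span / 3.0 if span > 0 else 1.0, c0


def fit_single_exponential(series: TimeSeriesCl, phase: str | None = None) -> ExpFit:
    """Free-asymptote single-exponential least-squares fit of a phase."""
    s = series.select_phase(phase) if phase else series
    t, y = s.t_s, s.cl_mM
    if len(t) < 4:
        raise ValueError("need at least 4 points for an exponential fit")
    t0 = float(t[0])
    if np.ptp(y) < 1e-12 * max(1.0, abs(float(y[0]))):
        return ExpFit(0.0, np.inf, float(y[0]), t0, 0.0, False,
                      flags=["degenerate: constant series, tau unidentifiable"])
    a0, tau0, c0 = _exp_initial_guess(t, y)
    tau_max = 1e4 * max(float(t[-1] - t0), 1.0)
    p = lmfit.Parameters()
    p.add("amplitude", value=a0)
    p.add("tau", value=float(np.clip(tau0, 1e-6, tau_max)), min=1e-9, max=tau_max)
    p.add("asymptote", value=c0)

    def resid(p):
        return (p["asymptote"].value
                + p["amplitude"].value * np.exp(-(t - t0) / p["tau"].value) - y)

    out = lmfit.minimize(resid, p, method="leastsq")
    flags = []
    tau = out.params["tau"].value
    if not out.success:
        flags.append("fit did not converge")
    if tau >= 0.99 * tau_max or tau <= 2e-9:
        flags.append("tau at bound")
    return ExpFit(out.params["amplitude"].value, tau,
                  out.params["asymptote"].value, t0,
                  float(np.sqrt(out.chisqr / len(t))), out.success, flags)


def fit_double_exponential(series: TimeSeriesCl, phase: str | None = None):
    """Diagnostic two-exponential fit; returns the lmfit result directly."""
    s = series.select_phase(phase) if phase else series
    t, y = s.t_s, s.cl_mM
    if len(t) < 6:
        raise ValueError("need at least 6 points for a double-exponential fit")
    t0 = float(t[0])
    a0, tau0, c0 = _exp_initial_guess(t, y)
    p = lmfit.Parameters()
    p.add("a1", value=a0 * 0.5)
    p.add("tau1", value=tau0 * 0.3, min=1e-9)
    p.add("a2", value=a0 * 0.5)
    p.add("tau2", value=tau0 * 3.0, min=1e-9)
    p.add("asymptote", value=c0)

    def resid(p):
        return (p["asymptote"] + p["a1"] * np.exp(-(t - t0) / p["tau1"])
                + p["a2"] * np.exp(-(t - t0) / p["tau2"]) - y)

    return lmfit.minimize(resid, p, method="leastsq")


def recovery_fraction(series: TimeSeriesCl, t_s: float) -> dict:
    """Normalised recovery measures at time t.

    Returns both conventions used for group summaries:

    * ``normalized_level`` — [Cl-]_i(t) / peak [Cl-]_i during loading;
    * ``fraction_recovered`` — (peak - [Cl-]_i(t)) / (peak - baseline),
      the fraction of the imposed load eliminated by time t.
    """
    if series.baseline_mM is None:
        raise ValueError("series needs a baseline_mM for recovery fractions")
    peak = series.peak_mM
    if peak is None or peak <= series.baseline_mM:
        raise ValueError("peak must exceed baseline")
    cl_t = interpolate_at(series, t_s)
    return {
        "normalized_level": cl_t / peak,
        "fraction_recovered": (peak - cl_t) / (peak - series.baseline_mM),
    }


def interpolate_at(series: TimeSeriesCl, t_s: float) -> float:
    """Linear interpolation between the two probes bracketing t."""
    t, y = series.t_s, series.cl_mM
    if not (t[0] <= t_s <= t[-1]):
        raise ValueError(f"t={t_s} s outside probed span [{t[0]}, {t[-1]}] s")
    return float(np.interp(t_s, t, y))


def probe_perturbation_bound(charge_C: float, v_equ_L: float) -> float:
    """[Cl-]_i change (mM) attributable to one probe's charge transfer.

    QC guard that probe applications are non-perturbing (the acceptance
    level used experimentally is < 1.0 mM per probe).
    """
    if v_equ_L <= 0:
        raise ValueError("equivalent volume must be positive")
    return abs(charge_C) / (FARADAY * v_equ_L) * 1e3
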