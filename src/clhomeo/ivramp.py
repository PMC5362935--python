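"""Ramp-sweep analysis: Rs correction, I-V construction, leak models,
reversal potentials and slope conductances.

The analysis chain mirrors offline voltage-clamp practice:

1. correct the command voltage for the series-resistance error,
   V_m = V_cmd - I * Rs;
2. re-grid ramp samples onto a uniform membrane-voltage axis (capacitive
   transients at ramp turning points blanked);
3. fit the agonist-free I-V with a linear or exponential
   (I = A + B e^(V/C)) leak model;
4. subtract the leak *model evaluated at the agonist sweep's corrected
   voltages* (not the raw trace) from the agonist I-V — this removes the
   bias that pointwise trace subtraction acquires when large agonist
   currents shift V_m through Rs;
5. read the reversal potential from the zero crossing and the slope
   conductance from a local OLS fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np

from .synthetic import Sweep

__all__ = [
    "LeakModel",
    "IVCurve",
    "correct_series_resistance",
    "build_iv_from_ramp",
    "fit_leak_model",
    "subtract_leak",
    "estimate_reversal_potential",
    "estimate_slope_conductance",
]


@dataclass
class LeakModel:
    """Fitted background (agonist-free) I-V model."""

    form: str  # "linear" | "exponential"
    slope_nS: float = np.nan
    intercept_pA: float = np.nan
    a_pA: float = np.nan
    b_pA: float = np.nan
    c_mV: float = np.nan
    v_min_mV: float = np.nan
    v_max_mV: float = np.nan
    rmse_pA: float = np.nan
    converged: bool = True
    warnings: list = field(default_factory=list)

    def predict(self, v_mV):
        v = np.asarray(v_mV, dtype=float)
        if self.form == "linear":
            return self.slope_nS * v + self.intercept_pA
        return self.a_pA + self.b_pA * np.exp(v / self.c_mV)


@dataclass
class IVCurve:
    """Current-voltage relation on a corrected, re-gridded voltage axis."""

    v_mV: np.ndarray
    i_pA: np.ndarray
    n_per_bin: Optional[np.ndarray] = None
    leak_subtracted: bool = False
    direction: str = "both"
    e_rev_mV: Optional[float] = None
    g_nS: Optional[float] = None
    g_window_mV: Optional[tuple] = None

    def __post_init__(self):
        v = np.asarray(self.v_mV, dtype=float)
        i = np.asarray(self.i_pA, dtype=float)
        if len(v) != len(i):
            raise ValueError("voltage and current must have equal length")
        if len(v) > 1 and np.any(np.diff(v) <= 0):
            raise ValueError("voltage grid must be strictly increasing")
        self.v_mV, self.i_pA = v, i


def correct_series_resistance(sweep: Sweep, rs_Mohm: float) -> np.ndarray:
    """Membrane voltage V_m = V_cmd - I * Rs, elementwise (mV)."""
    if rs_Mohm < 0:
        raise ValueError("series resistance must be non-negative")
    return sweep.v_cmd_mV - sweep.i_pA * rs_Mohm * 1e-3


def _turning_points(v_cmd: np.ndarray) -> np.ndarray:
    """Sample indices where the command ramp reverses direction."""
    dv = np.diff(v_cmd)
    sign = np.sign(dv)
    # ignore flat stretches when locating reversals
    nz = sign != 0
    idx = np.flatnonzero(nz)
    if len(idx) < 2:
        return np.array([], dtype=int)
    s = sign[idx]
    turns = idx[1:][s[1:] != s[:-1]]
    return turns + 1


def build_iv_from_ramp(sweep: Sweep, v_corrected_mV: np.ndarray,
                       t_start_s: float | None = None,
                       t_stop_s: float | None = None,
                       bin_mV: float = 1.0, blank_ms: float = 2.0,
                       direction: str = "both",
                       min_samples: int = 20,
                       intervals: list | None = None) -> IVCurve:
    """Bin ramp samples in [t_start, t_stop) onto a uniform voltage grid.

    Samples within ``blank_ms`` of a command turning point are excluded
    (capacitive transients). With ``direction`` "up" or "down" only the
    rising or falling half-ramps contribute; "both" averages them.
    ``intervals`` may give several (start, stop) pairs to pool instead of
    a single range.
    """
    if direction not in ("both", "up", "down"):
        raise ValueError("direction must be 'both', 'up' or 'down'")
    t = sweep.time_s
    if intervals is None:
        if t_start_s is None or t_stop_s is None:
            raise ValueError("give either t_start/t_stop or intervals")
        intervals = [(t_start_s, t_stop_s)]
    sel = np.zeros(len(t), dtype=bool)
    for a, b in intervals:
        sel |= (t >= a) & (t < b)
    if np.count_nonzero(sel) < min_samples:
        raise ValueError("selected segment too short")

    keep = sel.copy()
    blank_n = int(round(blank_ms * 1e-3 / sweep.sampling_interval_s))
    if blank_n > 0:
        for turn in _turning_points(sweep.v_cmd_mV):
            lo, hi = max(0, turn - blank_n), min(len(t), turn + blank_n + 1)
            keep[lo:hi] = False
    dv = np.gradient(sweep.v_cmd_mV)
    masks = {"up": keep & (dv > 0), "down": keep & (dv < 0)}
    if direction != "both":
        masks = {direction: masks[direction]}
    if sum(np.count_nonzero(m) for m in masks.values()) < min_samples:
        raise ValueError("too few samples left after blanking/direction filter")

    def bin_one(mask):
        v = v_corrected_mV[mask]
        i = sweep.i_pA[mask]
        idx = np.floor(v / bin_mV).astype(int)
        idx -= idx.min()
        nbins = idx.max() + 1
        counts = np.bincount(idx, minlength=nbins)
        v_sum = np.bincount(idx, weights=v, minlength=nbins)
        i_sum = np.bincount(idx, weights=i, minlength=nbins)
        good = counts > 0
        key = (np.floor(v / bin_mV).astype(int).min()
               + np.flatnonzero(good))  # absolute bin index
        return dict(zip(key, zip(v_sum[good] / counts[good],
                                 i_sum[good] / counts[good], counts[good])))

    binned = [bin_one(m) for m in masks.values() if np.count_nonzero(m)]
    if len(binned) == 2:
        # average the up- and down-limb curves bin-by-bin so symmetric
        # (e.g. capacitive) offsets cancel; keep bins present in both
        common = sorted(set(binned[0]) & set(binned[1]))
        if len(common) < 2:
            raise ValueError("up and down limbs share too few voltage bins")
        v_mean = np.array([(binned[0][k][0] + binned[1][k][0]) / 2 for k in common])
        i_mean = np.array([(binned[0][k][1] + binned[1][k][1]) / 2 for k in common])
        n = np.array([binned[0][k][2] + binned[1][k][2] for k in common])
    else:
        keys = sorted(binned[0])
        v_mean = np.array([binned[0][k][0] for k in keys])
        i_mean = np.array([binned[0][k][1] for k in keys])
        n = np.array([binned[0][k][2] for k in keys])
    order = np.argsort(v_mean)
    return IVCurve(v_mean[order], i_mean[order], n_per_bin=n[order],
                   direction=direction)


def fit_leak_model(iv: IVCurve, form: str = "exponential",
                   c_bounds_mV: tuple = (2.0, 200.0)) -> LeakModel:
    """Least-squares leak fit of the chosen form.

    The exponential fit is initialised from a linear pre-fit plus the
    local curvature; |C| is constrained to ``c_bounds_mV`` for numerical
    stability and both curvature signs (C > 0 and C < 0) are tried, the
    better fit kept. A non-converged exponential fit falls back to the
    linear model with a warning flag.
    """
    if form not in ("linear", "exponential"):
        raise ValueError("form must be 'linear' or 'exponential'")
    if len(iv.v_mV) < 10:
        raise ValueError("need at least 10 grid points for a leak fit")
    if iv.leak_subtracted:
        raise ValueError("leak fit requires an agonist-free (unsubtracted) curve")
    v, i = iv.v_mV, iv.i_pA
    slope, intercept = np.polyfit(v, i, 1)
    lin_pred = slope * v + intercept
    lin_rmse = float(np.sqrt(np.mean((i - lin_pred) ** 2)))
    lin = LeakModel("linear", slope_nS=slope, intercept_pA=intercept,
                    v_min_mV=v.min(), v_max_mV=v.max(), rmse_pA=lin_rmse)
    if form == "linear":
        return lin

    v_mid = float(np.mean(v))
    q2, q1, _ = np.polyfit(v, i, 2)
    c_lo, c_hi = c_bounds_mV

    def try_fit(c_sign):
        # curvature-matched initial C, clipped into the allowed band
        if q2 != 0 and np.sign((q1 + 2 * q2 * v_mid) / (2 * q2)) == c_sign:
            c0 = np.clip(abs((q1 + 2 * q2 * v_mid) / (2 * q2)), c_lo, c_hi) * c_sign
        else:
            c0 = 50.0 * c_sign
        b0 = slope * c0 * np.exp(-v_mid / c0)
        a0 = (intercept + slope * v_mid) - slope * c0
        p = lmfit.Parameters()
        p.add("a", value=a0)
        p.add("b", value=b0)
        p.add("c", value=c0, min=c_lo if c_sign > 0 else -c_hi,
              max=c_hi if c_sign > 0 else -c_lo)

        def resid(p):
            return p["a"].value + p["b"].value * np.exp(v / p["c"].value) - i

        return lmfit.minimize(resid, p, method="leastsq")

    results = []
    for sign in (+1, -1):
        try:
            results.append(try_fit(sign))
        except Exception:
            continue
    results = [r for r in results if r.success]
    if not results:
        lin.warnings.append("exponential fit failed; linear fallback used")
        lin.converged = False
        return lin
    best = min(results, key=lambda r: r.chisqr)
    a, b, c = (best.params[k].value for k in ("a", "b", "c"))
    model = LeakModel("exponential", a_pA=a, b_pA=b, c_mV=c,
                      v_min_mV=v.min(), v_max_mV=v.max(),
                      rmse_pA=float(np.sqrt(best.chisqr / len(v))))
    # monotonicity check: dI/dV = B/C e^{V/C} keeps the sign of B*C
    if b * c < 0:
        model.warnings.append("fitted exponential leak is decreasing in V")
    if model.rmse_pA > lin_rmse * (1 + 1e-9) :
        # exponential should never lose to its own nested linear limit by much
        model.warnings.append("exponential fit no better than linear")
    return model


def subtract_leak(iv_agonist: IVCurve, leak: LeakModel,
                  extrapolation_margin_mV: float = 10.0,
                  on_extrapolation: str = "warn") -> IVCurve:
    """Subtract the leak model evaluated at the agonist curve's voltages.

    Voltages outside the leak-fit domain by more than the margin trigger a
    warning (or ValueError with ``on_extrapolation='raise'``).
    """
    v = iv_agonist.v_mV
    if np.isfinite(leak.v_min_mV):
        over = max(leak.v_min_mV - v.min(), v.max() - leak.v_max_mV)
        if over > extrapolation_margin_mV:
            msg = (f"agonist voltages extend {over:.1f} mV beyond the "
                   f"leak-fit domain (margin {extrapolation_margin_mV} mV)")
            if on_extrapolation == "raise":
                raise ValueError(msg)
            warnings.warn(msg)
    return IVCurve(v.copy(), iv_agonist.i_pA - leak.predict(v),
                   n_per_bin=iv_agonist.n_per_bin, leak_subtracted=True,
                   direction=iv_agonist.direction)


def estimate_reversal_potential(iv: IVCurve,
                                regression_window_mV: float = 5.0) -> float:
    """Zero-current crossing of an I-V curve (mV).

    A single sign change is resolved by linear interpolation between the
    bracketing grid points. Multiple crossings (noise) trigger a local
    linear regression over +-``regression_window_mV`` around the crossing
    nearest the median crossing, with a warning.
    """
    v, i = iv.v_mV, iv.i_pA
    sign_change = np.flatnonzero(np.diff(np.signbit(i)))
    if len(sign_change) == 0:
        raise ValueError("current does not reverse within the voltage span")
    crossings = np.array([
        v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]) for k in sign_change
    ])
    if len(crossings) == 1:
        e_rev = float(crossings[0])
    else:
        warnings.warn(f"{len(crossings)} zero crossings; using local regression")
        center = crossings[np.argmin(np.abs(crossings - np.median(crossings)))]
        m = np.abs(v - center) <= regression_window_mV
        if np.count_nonzero(m) < 3:
            e_rev = float(center)
        else:
            slope, intercept = np.polyfit(v[m], i[m], 1)
            e_rev = float(-intercept / slope)
    iv.e_rev_mV = e_rev
    return e_rev


def estimate_slope_conductance(iv: IVCurve,
                               center_mV: float | None = None,
                               half_width_mV: float = 10.0) -> float:
    """OLS slope conductance (nS) of I on V over a voltage window.

    The window defaults to +-10 mV about the curve's reversal potential if
    known, else about the grid midpoint.
    """
    v, i = iv.v_mV, iv.i_pA
    if center_mV is None:
        center_mV = iv.e_rev_mV if iv.e_rev_mV is not None else float(np.mean(v))
    m = np.abs(v - center_mV) <= half_width_mV
    if np.count_nonzero(m) < 5:
        raise ValueError("fewer than 5 points in the conductance window")
    slope, _ = np.polyfit(v[m], i[m], 1)
    iv.g_nS = float(slope)
    iv.g_window_mV = (center_mV - half_width_mV, center_mV + half_width_mV)
    return float(slope)
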