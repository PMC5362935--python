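"""Nernst relations for chloride and solution bookkeeping.

In HCO3-free solutions the reversal potential of GABA_A/glycine-receptor
currents equals the chloride equilibrium potential E_Cl, so measured
reversal potentials translate directly into intracellular chloride
concentrations through the (anionic) Nernst equation

    E_Cl = (RT/F) ln([Cl-]_i / [Cl-]_o)

with a fixed, configurable additive offset for the liquid-junction
potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import thermal_voltage_mV

__all__ = [
    "NernstContext",
    "nernst_potential_mV",
    "chloride_from_potential_mM",
    "solution_chloride",
    "CL_STOICHIOMETRY",
]

#: Cl- ions contributed per formula unit of recognised salts.
CL_STOICHIOMETRY = {
    "NaCl": 1,
    "KCl": 1,
    "CaCl2": 2,
    "MgCl2": 2,
    "CdCl2": 2,
    "CsCl": 1,
    "HCl": 1,
    "LiCl": 1,
    "TEA-Cl": 1,
    "choline-Cl": 1,
    "NH4Cl": 1,
    "BaCl2": 2,
}


@dataclass(frozen=True)
class NernstContext:
    """Fixed quantities needed to convert E_Cl <-> [Cl-]_i.

    Parameters
    ----------
    cl_out_mM : extracellular chloride concentration (mM).
    temperature_K : absolute temperature; default 295 K (room temperature).
    offset_mV : additive voltage offset (e.g. residual junction potential)
        applied to computed potentials and removed before inversion.
    """

    cl_out_mM: float
    temperature_K: float = 295.0
    offset_mV: float = 0.0

    def __post_init__(self):
        if self.cl_out_mM <= 0:
            raise ValueError("extracellular chloride must be positive")
        if not (273.0 <= self.temperature_K <= 320.0):
            raise ValueError("temperature outside supported range [273, 320] K")

    def nernst(self, cl_in_mM):
        return nernst_potential_mV(
            cl_in_mM, self.cl_out_mM, self.temperature_K, self.offset_mV
        )

    def chloride(self, e_cl_mV):
        return chloride_from_potential_mM(
            e_cl_mV, self.cl_out_mM, self.temperature_K, self.offset_mV
        )


def nernst_potential_mV(cl_in_mM, cl_out_mM, temperature_K=295.0, offset_mV=0.0):
    """Chloride equilibrium potential (mV), anion sign convention."""
    cl_in = np.asarray(cl_in_mM, dtype=float)
    if np.any(cl_in <= 0) or cl_out_mM <= 0:
        raise ValueError("concentrations must be positive")
    e = thermal_voltage_mV(temperature_K) * np.log(cl_in / cl_out_mM) + offset_mV
    return float(e) if np.isscalar(cl_in_mM) else e


def chloride_from_potential_mM(e_cl_mV, cl_out_mM, temperature_K=295.0, offset_mV=0.0):
    """Exact inverse of :func:`nernst_potential_mV`."""
    if cl_out_mM <= 0:
        raise ValueError("extracellular chloride must be positive")
    e = np.asarray(e_cl_mV, dtype=float) - offset_mV
    cl = cl_out_mM * np.exp(e / thermal_voltage_mV(temperature_K))
    return float(cl) if np.isscalar(e_cl_mV) else cl


def solution_chloride(composition) -> float:
    """Total [Cl-] (mM) of a solution given as (salt, mM) pairs.

    Only chloride-containing salts with known stoichiometry are accepted;
    an unknown salt name raises ``KeyError``. An empty composition gives 0.
    """
    total = 0.0
    for salt, conc_mM in composition:
        if salt not in CL_STOICHIOMETRY:
            raise KeyError(f"unknown salt {salt!r}; add it to CL_STOICHIOMETRY")
        if conc_mM < 0:
            raise ValueError("salt concentration must be non-negative")
        total += CL_STOICHIOMETRY[salt] * conc_mM
    return total
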