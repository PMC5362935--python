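"""Physical constants and unit helpers.

External unit conventions (matching common electrophysiology practice):
voltages in mV, currents in pA, conductances in nS (so pA = nS * mV),
series resistance in MOhm (voltage error mV = MOhm * pA * 1e-3),
concentrations in mM, volumes in litres, time in seconds.
"""

R_GAS = 8.314  # J mol-1 K-1
FARADAY = 96485.0  # C mol-1


def thermal_voltage_mV(temperature_K: float) -> float:
    """RT/F in millivolts (~25.4 mV at 295 K)."""
    return R_GAS * temperature_K / FARADAY * 1e3
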