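"""Miniature synaptic conductance trains and their effect on recovery.

Simulates Poisson trains of difference-of-exponential conductance events
(mIPSC-like) and feeds their time-varying conductance into the chloride
model on top of the 54 pS resting conductance. Prolonging the event decay
(as a neurosteroid does) raises the mean chloride conductance and quickens
conductive [Cl-]_i recovery at -74 mV.
"""

import numpy as np

import clhomeo as c

state = c.CellState(g_kcc2=0.0)  # KCC2 blocked: conductive recovery only
duration = 600.0
print(f"{'condition':<22}{'mean g (pS)':>12}{'[Cl-] @10 min (mM)':>20}")
for label, decay in [("control minis", 0.020), ("prolonged decay x3", 0.060)]:
    train = c.MiniTrain(rate_Hz=2.0, peak_g_nS=0.5, decay_tau_s=decay,
                        rise_tau_s=0.001, duration_s=duration)
    trace = c.simulate_mini_train(train, seed=42, dt_s=0.05)
    g_sched = state.g_cl_pS + trace.g_nS * 1e3  # resting + mini conductance
    res = c.simulate(state, duration, dt_s=0.05, modes="conductive",
                     g_cl_pS=g_sched)
    print(f"{label:<22}{np.mean(g_sched):12.0f}{res.final_cl_mM():17.1f}")
res0 = c.simulate(state, duration, dt_s=0.05, modes="conductive")
print(f"{'no minis':<22}{state.g_cl_pS:12.0f}{res0.final_cl_mM():17.1f}")
# Event statistics here are user-set placeholders (no study values exist);
# the comparison shows the mechanism, not a quantitative prediction.
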