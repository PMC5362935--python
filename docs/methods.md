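# Methods

## The measurement problem

In bicarbonate-free solutions the GABA_A/glycine-receptor reversal potential
equals the chloride Nernst potential, E_Cl = (RT/F)·ln([Cl⁻]ᵢ/[Cl⁻]ₒ), so a
brief agonist "probe" combined with a voltage ramp reads out [Cl⁻]ᵢ. Two
quantities built on this readout are implemented here: the time course of
[Cl⁻]ᵢ recovery after a large chloride load, and the chloride share of the
resting membrane conductance.

## Ramp analysis

**Series resistance.** The pipette access resistance Rs (typically
15–40 MΩ) makes the true membrane voltage V_m = V_cmd − I·Rs. The analysis
corrects voltages offline from the recorded current; the synthetic
generator solves the same fixed-point relation per sample (vectorised
Newton, residual < 1e−9 mV), so correction against generator truth is exact
in the noiseless limit.

**I–V construction.** Ramp samples are averaged into 1 mV voltage bins
(configurable). Rising and falling limbs are binned separately and the two
curves averaged bin-by-bin, which cancels symmetric capacitive offsets
exactly; samples within 2 ms of a ramp turning point are blanked. Published
reports rarely state binning/blanking choices, so both are exposed as
parameters and reported in outputs.

**Leak subtraction.** The agonist-free I–V is fitted with a linear model or
with I = A + B·e^{V/C}. The fitted *model is then evaluated at the agonist
sweep's own corrected voltages* and subtracted. This matters with Rs:
agonist currents displace V_m, so pointwise trace subtraction compares
currents at different true voltages and biases the difference curve; model
evaluation does not (both routes are contrasted in the test suite). The
exponential fit is initialised from a linear pre-fit plus local curvature,
|C| is bounded to [2, 200] mV for stability (both curvature signs are
tried), and non-convergence falls back to the linear form with a flag. For
a cell known to be ohmic, the linear form should be selected; the bounded
exponential then only approximates a line to ~2 % of the current range.

**Reversal and slope.** E_rev is the zero crossing, by linear interpolation
between the bracketing bins; if noise creates several crossings, a local
regression over ±5 mV around the crossing nearest the median is used and a
warning emitted. Slope conductance is an OLS fit over a window (default
±10–15 mV about the holding level or reversal).

## The resting-g_Cl estimator

With the resting potential written in the conductance (GHK) form,
E_rev = Σ(g_x/g_T)·E_x, the Na⁺/K⁺ terms cancel between two measurements if
the conductances and E_Na/E_K are constant, leaving
g_Cl/g_T = ΔE_rev/ΔE_Cl. This identity is exact for an ohmic membrane and
is verified numerically (including the zero-crossing numerics) over
g_Cl/g_T ∈ {0…0.2} × ΔE_Cl ∈ {10, 30, 50} mV.

`run_gcl_protocol` realises it on a four-phase protocol: (1) ramps around
−74 mV give g_T1, E_rev1 from agonist-free trains and E_Cl1 from a flanked
probe; (2) a 20 s agonist application at −14 mV loads the cell to ~60 mM,
E_Cl2a being read from the last second of the application; (3) a second
−74 mV train gives g_T2, E_rev2; (4) a final probe around −34 mV gives
E_Cl2b. E_Cl at the g_T2 time is interpolated linearly between E_Cl2a and
E_Cl2b (measurement times are taken as interval midpoints — the exact
read-out instants within a train are an open choice). QC fails the estimate
when |g_T2 − g_T1|/g_T1 ≥ 30 %; failed or out-of-[0, 1] estimates are
flagged, never clipped or truncated, so group means stay unbiased.

Because the recording cocktail (TEA, Cd²⁺, TTX, KCC2 blocker) lowers the
total conductance to ~54 % of its blocker-free value, both bases are always
reported: the in-blockers ratio and the blocker-free ratio (in-blockers ×
factor, default 0.54, configurable). Absolute g_Cl is the in-blockers ratio
times the mean of g_T1/g_T2.

## Single-compartment chloride model

State: [Cl⁻]ᵢ in an equivalent cytosolic volume v_equ (the volume in which
the measured charge transfer explains the observed concentration change,
v_equ = Q·F⁻¹·Δ[Cl⁻]ᵢ⁻¹ ≈ 5×10⁻¹³ L, half a 6.2 µm sphere). Per Euler step
Δt (default 50 ms):

- KCC2: Δ[Cl⁻]ᵢ = −Δt·Δµ_K,Cl·g_KCC2/v_equ, with
  Δµ_K,Cl = RT(ln([Cl⁻]ᵢ/[Cl⁻]ₒ) + ln([K⁺]ᵢ/[K⁺]ₒ)). Electroneutral and
  voltage-independent; fixed point [Cl⁻]ₒ[K⁺]ₒ/[K⁺]ᵢ ≈ 5.05 mM.
- Conductive: Δ[Cl⁻]ᵢ = I·Δt/(F·v_equ) with I = g_Cl(V_m − E_Cl); fixed
  point E_Cl = V_m. V_m and g_Cl accept schedules (arrays or callables), so
  loading phases and mini-trains can be superimposed.

All other pools are fixed (no volume change, no HCO₃⁻, no NKCC1 term —
the membrane potential is imposed, as under voltage clamp). Defaults:
[Cl⁻]ₒ 146.4 mM (the stoichiometric chloride of the recording solution:
137 NaCl + 5 KCl + 2×1 CaCl₂ + 2×1.2 MgCl₂), [K⁺]ᵢ 145 mM, [K⁺]ₒ 5 mM,
T 295 K (room temperature), baseline [Cl⁻]ᵢ 9 mM, g_Cl 54 pS,
g_KCC2 6.7×10⁻²¹ mol² V⁻¹ C⁻¹ s⁻¹ (the transporter factor that matches
measured KCC2-mediated recovery). The combined steady state is found by
bisection between the two closed forms. The integrator enforces [Cl⁻]ᵢ > 0
and aborts with a diagnostic otherwise. A 50 ms step tracks a 1 ms
reference within 1 % of the dynamic range at these parameters (verified
over a 600 s horizon covering the fast phase; an adaptive `solve_ivp`
reference serves as an independent oracle in the tests).

Note the KCC2 flux is linear in the *logarithm* of [Cl⁻]ᵢ, so a strong-load
recovery is not exponential: it is near-linear early and steepens near the
fixed point. A free-asymptote single-exponential fit of the 0–1500 s
KCC2-only trajectory therefore yields τ ≈ 570 s with a slightly negative
asymptote — a summary statistic, not a model parameter.

## Recovery summaries

Single-exponential fits y(t) = asymptote + amplitude·e^{−(t−t₀)/τ} use a
log-linear pre-fit for initialisation, a free asymptote (whether published
fits constrained it is unknown; free is the default) and unweighted least
squares. Degenerate (constant) series and bound-hitting τ are flagged. A
double-exponential variant exists for diagnostics only. Two normalisations
are exposed: level relative to the loading peak, and fraction of the load
eliminated, (peak − y)/(peak − baseline); the latter is affine-invariant.
The fitted asymptote matches the analytic steady state within 5 % only in
the near-exponential (small-perturbation) regime, and the tests check it
there. `probe_perturbation_bound` converts a probe's integrated agonist
charge into a [Cl⁻]ᵢ bound (acceptance level < 1 mM per probe).

## Synthetic data: what it emulates and what it does not

Each sample's current is leak(V_m) + (g_Cl,rest + g_ag(t))(V_m − E_Cl) +
noise, with the agonist conductance relaxing toward its target through a
first-order solution-exchange filter (τ = 50 ms) and optional sample-level
coupling of [Cl⁻]ᵢ to the chloride-carried current (chunked per half-cycle;
the E_Cl drift per 25 ms chunk is far below one voltage bin). Noise is
additive i.i.d. Gaussian on current (default 5 pA SD); V_m is solved from
the noiseless current, and measurement noise is added afterwards. The
default cell carries 54 pS of chloride conductance in a 0.48 nS total
(in-blockers conditions) at 20 MΩ Rs; the default agonist conductance
(7.5 nS) is set so the 20 s loading window ends near the study-scale
~60 mM load from a 9 mM baseline. Coupled sweeps advance chloride by the
channel flux only, mirroring the KCC2-blocked conditions of the g_Cl
protocol.

Not emulated: receptor desensitisation and pharmacology (drug conditions
are represented only as different true conductances), stochastic channel
gating, capacitance transients beyond what blanking removes, cell-to-cell
variability in leak shape, multicompartment geometry, and amplifier
artefacts. Mini-train event statistics (rate 2 Hz, peak 0.5 nS, rise 1 ms,
decay 20 ms) are exploratory placeholders, not measured values. Passing
tests on these fixtures validate the numerics and the estimator's
self-consistency, not the biological accuracy of any particular recording.

## Problem sizes and numerical defaults

Sweeps are generated at 10 kHz; the g_Cl protocol spans 48 s (~0.5 M
samples) and a Monte-Carlo assessment uses 50 seeds. Model trajectories use
Δt = 50 ms over 1500 s horizons (3000 s where a fixed point must be
reached to 0.1 %). Tolerances asserted in the tests: noiseless estimator
recovery to 0.005 absolute; noisy end-to-end median error < 0.01; steady
states to 0.1 %; Euler step consistency to 1 % of range.
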