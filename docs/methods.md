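# Methods

## GLT-1 kinetic scheme

The transporter is a six-state cycle C1→C2→…→C6→C1 (forward = uptake):
extracellular glutamate binds C1→C2 (k12·[Glu]ₒ), extracellular Na⁺ binds
C2→C3 (k23·[Na]ₒ), translocation C3→C4, intracellular release C4→C5
(reverse rate k54·[Glu]ᵢ), Na⁺ release C5→C6 (reverse k65·[Na]ᵢ), and the K⁺
counter-transport limb C6→C1 (k61·[K]ᵢ) with reverse C1→C6 (k16·[K]ₒ).
Charge-moving rates carry u(V, P) = exp(P·V/53.4) with partial charges
P₁₂ = −0.1, P₂₃ = 0.5, P₃₄ = 0.4, P₅₆ = 0.6 and P₁₆ on the K⁺-binding step.
Rate constants (ms⁻¹, mM⁻¹ms⁻¹ for second-order): k12 = 20, k21 = 0.1,
k23 = 0.015, k32 = 0.5, k34 = 0.2, k43 = 0.6, k45 = 4, k54 = 10, k56 = 1,
k65 = 0.1, k16 = 0.0016, k61 = 2·10⁻⁴. Ion defaults: Na 15/150, K 120/3,
Glu 0.3/0 mM (in/out). Current density:
I = −e·den·Σ P_ij·(net flux i→j), den = 10⁴ µm⁻², inward uptake negative.

### Dialect switches and why they exist

The published parameterisation leaves four genuinely open readings, all
isolated behind switches on `GLT1Params`:

* **P₁₆ placement** (`p16_rate` vs `p16`). The source kinetics print
  u(V, 0.6) in the C16 rate, but the fitted model "reduced the voltage
  sensitivity of the K⁺-binding step from 0.6 to 0.1". That modification can
  be read as applying to the rate's u-exponent, to the current-equation
  charge coefficient, or to both. The library defaults to the fitted 0.1 in
  both places (the thermodynamically consistent reading). The zero-current
  solver defaults to the one combination that actually reproduces the
  published reversal concentration at [K]ₒ = 5 mM to within ~15%: rate keeps
  u(V, 0.6), current carries charge 0.1 (`reversal_dialect_params()`); every
  other combination is off by one to two orders of magnitude. That
  combination is therefore recorded as the reversal dialect.
* **Current-equation form** (`current_dialect`). `"consistent"` evaluates
  charge-weighted fluxes with exactly the generator's rates, so the
  steady-state current equals net cycle flux × total cycle charge × e × den
  (verified against an independent cycle-flux oracle to 10⁻⁹). `"printed"`
  reproduces the published expression literally (no u-factor on the k34 term,
  fixed u(V, 0.6) on the k16/k56 terms). The two differ only transiently and
  near the reversal point.
* **Voltage-sign convention** (`voltage_sign`). As printed, u(V, P) makes
  inward-positive-charge transitions *faster* with depolarisation, so steady
  uptake current grows from −85 to −40 mV — opposite to the experimentally
  observed suppression of uptake in depolarised astrocytes. The
  `voltage_sign = −1` (thermodynamic) convention restores the physical
  monotonicity; the default stays at the printed convention, and the
  property suite asserts the monotonicity under the thermodynamic convention
  while documenting the printed inversion.
* **Reversal voltage policy** (`v_policy`). The voltage at which the
  published reversal concentrations were computed is unstated. Default:
  the astrocyte resting potential at the given [K]ₒ from the membrane model
  (this couples K⁺ to depolarisation, the mechanism under study); a fixed
  −85 mV policy is selectable. Both land within a few percent of each other.

The published reversal value at [K]ₒ = 2.5 mM (3.57·10⁻⁶ mM) could not be
reproduced under *any* dialect: every steady-state reading of a single-cycle
scheme scales the stall concentration roughly linearly in [K]ₒ (ratio ≈ 2
between 5 and 2.5 mM), whereas the two published values differ 23.8-fold.
Our computed value at 2.5 mM, 3.49·10⁻⁵ mM, agrees with 3.57·10⁻⁵ to ~2%,
so we treat the published exponent as a misprint; the acceptance test still
asserts against the value as printed and fails, by design.

### Numerics

Steady state is the null space of the transposed generator (SVD), normalised
to the simplex; residual ‖p·Q‖∞ < 10⁻⁹ enforced. Transients use implicit
Euler (I − dt·Qᵀ)p⁺ = p: unconditionally stable for the stiff rate span
(2·10⁻⁴ … 20 ms⁻¹), exactly probability-conserving, positivity-preserving,
and its fixed point is the exact stationary distribution. dt = 0.01 ms during
glutamate boluses, 0.1 ms otherwise. The reversal solver brackets
[10⁻⁹, 1] mM and uses Brent's method (rtol 10⁻¹³).

## Astrocyte membrane

I_Kir = G_Kir·c([K]ₒ)·(V − NK·E_K − V_A1)/(1 + exp((V − NK·E_K − V_A2)/V_A3))
with G_Kir = 0.1 mS cm⁻², V_A1 = −14.83, V_A2 = −105.82, V_A3 = 19.23 mV,
NK = 0.81; leak G_pas = 0.001 mS cm⁻², E_pas = −85 mV. The published
concentration factor is garbled; the default dialect is c = √([K]ₒ/K_ref)
with K_ref = 3 mM (the square-root conductance scaling typical of Kir4.1),
with linear and constant dialects selectable (`kir_k_factor`). C_m = 1 µF
cm⁻² (standard, unstated in the source). Nernst slope 26.7 mV = 53.4/2, so
the membrane and transporter share one voltage convention; an RT/F-at-307-K
option (26.46 mV) exists. The Kir current is zero exactly at
V = NK·E_K + V_A1 (at [K]ₒ = 3 mM that is −94.6 mV; the resting potential,
where Kir balances the leak, is −88.8 mV). With these parameters the
denominator exceeds ~100 at physiological voltages, so the effective Kir
conductance is of order G_pas and the peak Kir density during the K⁺ bolus
is ~3·10⁻⁶ mA cm⁻² — three orders below the ~0.01 mA cm⁻² quoted alongside
the garbled equation; we log it as a diagnostic rather than asserting it.

## Reduced hotspot simulation

The morphology is a statistical stand-in, not a reconstruction: a spherical
soma (8 µm), 6 branches of 8 tapering segments (2→0.4 µm) to a 45 µm arbor
radius, and 8 nanoscopic leaflets per segment (0.1–0.3 µm diameter,
1–3 µm length), regenerated until the whole-cell surface-to-volume ratio
falls in a configured band (default 1.8–12 µm⁻¹; seed-deterministic,
~433 compartments). Axial resistivity 150 Ω·cm.

Per time step: batched implicit-Euler occupancy update per compartment
against the local fields; transporter current from the occupancies; membrane
voltage by backward-Euler cable solve (axial Laplacian implicit and
pre-factorised, membrane currents explicit — the membrane time constant is
~0.5 s, far above dt); intracellular K⁺ with the Kir source −I_Kir·A/(F·Vol)
and longitudinal diffusion D_K = 0.6 µm² ms⁻¹ (the published "0.6 mm/ms²"
read as a physical diffusion coefficient). Cumulative Kir charge equals
F × K⁺ gained exactly by construction; the test suite verifies it per
compartment with diffusion off and cell-wide with diffusion on. Extracellular
fields are prescribed homogeneous spheres (no extracellular PDE), with an
optional exponential skirt (off by default). The glutamate bolus defaults to
1 ms (the figure-generating protocol; 2 ms selectable).

The hotspot readout volume-averages the transporter current density over
compartments whose centre lies inside the glutamate sphere, measures the
inward peak from the pre-bolus baseline, and fits a decay constant.

### What the model does and does not reproduce

With the printed parameters the paired experiment gives ~10.7% suppression
of the hotspot peak (seed 1; published figure ~15%). Decomposition by
voltage clamp shows ~11.3% suppression survives clamping at −85 mV: the
effect is dominated by extracellular K⁺ binding (doubling [K]ₒ doubles the
C1→C6 rate and sequesters transporters in the K⁺-bound states C6/C5 before
the bolus), while the Kir-mediated depolarisation under the sqrt dialect is
only ~0.5 mV and — under the printed voltage convention — slightly *opposes*
the suppression. The experimental dissociation (clamped astrocytes
insensitive to [K]ₒ; depolarisation alone suppresses uptake) is therefore
not a property of this reduced model at these printed parameters, and the
corresponding acceptance check is expected to fail; we report this rather
than re-tuning constants. The suppression magnitude itself is robust: it is
insensitive to halving both time steps (< 1 percentage point), to the
morphology seed (< 0.2 points across seeds), and sign-consistent at all 10
recording distances inside the K⁺ sphere.

## Trace analysis and synthetic recordings

Synthetic recordings sum two inward difference-of-exponentials components —
transporter: rise 1 ms, decay 5.75 ms, peak 10 pA; K⁺ current: rise 10 ms,
decay 300 ms — plus white Gaussian noise, at dt = 0.1 ms (10 kHz). Train
protocols (5 × 50 Hz) apply per-stimulus facilitation (1, 1.4, 1.8, 2.1,
2.3) and decay-prolongation multipliers (up to 4.1×, emulating the observed
use-dependent prolongation ≈ 23.65/5.75). Per cell, the blocker-template
trace is the K⁺ component rescaled by a lognormal factor with its own noise.
All randomness flows from one seed. What the generator does *not* emulate:
stimulus artifacts, pink/line noise, series-resistance errors, release
stochasticity — so pipeline tests demonstrate correctness of the estimators,
not robustness to every recording pathology.

Pipeline defaults, validated on this ground truth:

* **Tail window for template scaling**: 150–450 ms after the last stimulus.
  150 ms clears even 4×-prolonged transporter decays to < 0.2% of peak while
  the slow K⁺ tail is still large, keeping the least-squares scale
  well-conditioned (recovered to ~10⁻⁹ noise-free, ~0.6% at SNR 10).
* **Decay fit**: monoexponential, window from 70% of peak (skipping
  rise-phase contamination near the extremum) to 98% recovery, baseline
  anchored at the median of the final 10% of the record. Anchoring the
  baseline rather than fitting it cuts the tau estimator's spread ~10-fold
  under noise (mean 5.97 vs 7.17 ms at SNR 10, truth 5.75). Peak and window
  detection run on a 0.5 ms-smoothed copy; the fit itself uses raw samples.
  A free-baseline variant remains selectable.
* **Train peaks**: amplitude of each response measured against the
  exponential extrapolation of the preceding inter-stimulus decay
  (a pre-stimulus-value baseline is selectable and measurably worse under
  overlap), normalised to the single-stimulus amplitude.
* **K⁺-current amplitude**: mean over a 20 ms window centred 200 ms after
  the last response peak (peak searched within 50 ms of the last stimulus),
  pre-stimulus baseline subtracted.

## Problem sizes

Default study sizes were chosen so any single driver completes in minutes on
one CPU: 433 compartments, 1 s simulated per hotspot run, 10 distance sites
(20 paired runs), 200 synthetic experiments per pipeline validation. All are
parameters, not constants.

## Known limitations

* The reduced morphology is near-isopotential (electrotonic length ≫ arbor
  radius at the printed conductances), so spatial voltage confinement and
  leaflet-specific depolarisation are not represented; conclusions about
  voltage-mediated suppression in intact tissue should not be drawn from it.
* Extracellular fields are prescribed; no electrodiffusion, tortuosity or
  uptake-driven depletion of the bolus.
* The transporter model omits H⁺ co-transport and the anion-conductance mode,
  and its printed charge assignments are not thermodynamically consistent
  (see the voltage-sign dialect above); reversal concentrations should be
  read as model properties, not physical free-energy calculations.
* Na⁺/K⁺-ATPase, NKCC1 and gap junctions are absent, so intracellular K⁺
  recovery after the bolus is purely diffusive/Kir-mediated.
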