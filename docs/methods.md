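# Methods

## Scope and model chain

The package models one question end to end: *how much thermal dose does a
given sonication protocol deposit in focal uterine adenomyosis, and how do
the clinical efficacy indices built on top of such treatments behave?*
The chain is

1. linear acoustics of a focused bowl source →
2. absorbed-power heating and the Pennes bioheat equation →
3. CEM43 thermal dose and ablated volume per treatment protocol →
4. outcome metrics (volume, AVSR, NPVR, DII) on participant records,
   generated synthetically.

Nonlinear acoustics (harmonics, shock formation), cavitation, aberration
correction, tissue-property changes with temperature, perfusion shutdown
on coagulation, and organ motion are out of scope throughout.

## Acoustic model

**Source.** The treatment head is modelled as a uniformly driven
spherical-cap bowl, default focal length 130 mm, aperture radius 64 mm,
center frequency 1.0 MHz — a representative abdominal-HIFU geometry; the
true device aperture and element layout are not published, so the bowl is
configuration, never a claim.  The cap is tiled into sub-elements:
azimuthal arcs at most `max_subelement` (default λ/2 in water) wide, and
meridional bands at *half* that pitch, because the axial interference
structure is far more sensitive to the θ quadrature than to φ.  Rings sit
at each band's area centroid, and band areas are exact, so the tiling
reproduces the analytic cap area 2πR(R−√(R²−a²)) to round-off.

**Rayleigh–Sommerfeld sum.** Pressure is the discrete Rayleigh integral
p = (iρck/2π) Σ u ΔS e^{−(ik+α)r}/r with one correction: each flat
sub-element carries a directivity factor sinc(k·w_u·s_u/2)·sinc(k·w_v·s_v/2)
(s_u, s_v the direction cosines onto the element tangents), which
integrates the linear phase ramp across the element exactly.  Without it
the midpoint rule needs roughly 4× finer tiling for the same accuracy.
Against the closed-form axial solution of a focused cap (carried in
`oneil_on_axis_pressure`; valid for complex k) the default tiling is
accurate to ≲0.3 % of the local axial pressure over [0.5F, 1.5F],
including deep interference minima.  The pairwise sum is JIT-compiled
with numba when available; a numpy path computes the identical expression
otherwise.

**Angular spectrum.** Plane-to-plane marching uses the standard spectral
propagator e^{−ik_z dz} with zero-padding factor 2 against wrap-around,
hard truncation of evanescent components, per-step amplitude attenuation
e^{−α dz}, and an optional angular-restriction filter (off by default).
A hybrid driver seeds the shallowest plane of a volume with the
Rayleigh–Sommerfeld sum and marches through the rest; on a 128² test case
the hybrid field agrees with direct RS evaluation to <0.1 % in the −6 dB
focal region.

**Intensity and calibration.** I = |p|²/(2ρc) (plane-wave relation).
The preset "focal intensity" is interpreted as the *in-situ spatial-peak,
pulse-average* intensity: the simulated template field is normalized so
its peak equals the preset value during the on-phase of the duty cycle.
A free-field interpretation would only rescale both presets by the same
factor and cannot change any A-vs-B comparison.

## Tissue and bioheat model

**Beam path and properties.** Default layered path water / 10 mm fat /
15 mm muscle / myometrium to the focus, with literature-typical acoustic
constants (c = 1482/1450/1580/1540 m/s, ρ = 994/950/1050/1050 kg/m³,
α = 0.002/0.48/0.74/0.50 dB/cm at 1 MHz, power-law exponent 1.1,
absorption fraction 0.9).  Thermal defaults k = 0.56 W/m/K, ρ = 1050
kg/m³, c_p = 3600 J/kg/K, c_b = 3617 J/kg/K, T_a = 37 °C.  The perfusion
dichotomy is the scientifically load-bearing choice: fibroids perfuse
like skeletal muscle (w_b = 0.7 kg/m³/s) while adenomyosis perfuses like
the myometrium (w_b = 2.5 kg/m³/s).  The *identification* (which tissue
maps to which reference) and the direction (myometrium ≫ muscle) are the
modelled claims; the numeric values are declared, overridable defaults.

**Solver.** Explicit forward-time centered-space on a uniform voxel grid
(default 0.5 mm; the acoustic template is computed at 2× transverse
resolution and block-averaged down).  Stability is guarded by
dt ≤ ρc_p/(6k/dx² + w_b c_b); an unstable request raises with a suggested
step.  Domain faces are clamped to T_a.  Verified limits: equilibrium is
preserved to 1e-12; with k = 0 a uniform offset decays as
exp(−w_b c_b t/ρc_p) to <1e-3 relative; with w_b = 0 a Gaussian hot spot
spreads with the heat-kernel variance law to <1 % peak error over one
diffusion time; a source-free, perfusion-free run obeys the discrete
maximum principle.

**Thermal dose.** CEM43 = Σ R^{43−T} Δt, R = 0.5 at or above 43 °C and
0.25 below, ablation at ≥ 240 equivalent minutes (inclusive).  These are
the standard conventions; the dose is accumulated every solver step, is
exactly additive over split histories, and `ablated_volume` counts voxels
at or above threshold.

## Treatment replay

`plan_grid` lays a cubic lattice at the preset's point interval over the
lesion ellipsoid, excluding the deepest 10 mm ("one centimeter above the
deepest margin" read as an exclusion slab — the most conservative
interpretation; the offset is configurable).  Raster order is
shallow-to-deep planes with boustrophedon rows; the order is declared
because near-field preheating makes dose mildly order-dependent, and no
particular order is claimed for the device.

`simulate_treatment` computes one acoustic template per grid and
translates it to each point (homogeneous focal neighborhood assumption;
per-point re-solves would change nothing on these millimetre-scale
translations but cost orders of magnitude more).  Heating runs
per-point-time with the duty-scaled source, then the transition time with
the source off; no transition follows the last point, so the protocol
duration is exactly n·t_point + (n−1)·t_trans and on-time is
n·t_point·duty.

**Duty-cycle modelling.** Default is time-averaged heating (Q × duty):
the 100 ms pulse period is two orders of magnitude below the focal spot's
thermal time constant.  Explicit 10 Hz gating is available; it agrees
with the averaged model on the ablated volume to a few percent.  The
*pointwise* dose at the focal peak is systematically higher under
explicit pulsing (the dose rate is exponential in T, so symmetric ±ΔT
ripples do not cancel); the ablation boundary, where gradients are
shallow, is insensitive to this.  Comparisons between protocols use the
same mode on both sides and are unaffected.

## Parameter comparison

`compare` evaluates each parameter set on each tissue scenario with a
standardized single-point plan (isolating per-point physics from raster
coverage; a 3×3 mini-grid mode exposes the 2 mm vs 4 mm contiguity
effect), reporting peak temperature, peak CEM43, ablated volume, and
ablated volume per protocol minute.  No objective function is singled
out: the report exposes all three axes along which the optimized set was
argued to be better.  `perfusion_sweep` re-runs the bioheat stage across
perfusion values on a shared acoustic template; the resulting curve is
monotone non-increasing, and a sufficiently large sink drives the peak
dose below the 240 min threshold — no lesion forms, which is the failure
mode the optimized parameters address.

On the default grid the single-point comparison gives ~0.0195 cm³ (A) vs
~0.0515 cm³ (B) ablated per point on adenomyosis perfusion.  Problem
sizes used throughout (56×56×80 voxels at 0.5 mm, 128² seed planes,
single-point or 10-point plans) were chosen as the smallest grids on
which the focal spot and dose contour are resolved; all sizes are
configuration.

## Outcome metrics

Volume = 0.523·L·W·H from three orthogonal axes (0.523 ≈ π/6 on full
axis lengths).  AVSR = 100·(1 − V_after/V_before), negative for growth.
NPVR = 100·NPV/reference; the reference is the original (pre-treatment)
volume by definition and by default, but a same-timepoint reference mode
is provided because published worked examples occasionally use it — with
NPV = 8.3 cm³ and a same-timepoint volume of 12.0 cm³ this package
computes 69.2 % (69.17 rounded half away from zero; a printed value of
69.1 % for this configuration cannot be reproduced exactly under either
rounding rule and is not asserted anywhere).  Clinically effective DII is
score ≤ 3 on the 1–5 improvement scale.  Summaries report medians with
quartiles 1–3 (linear-interpolation convention, fixed for determinism)
and effective-DII percentages with count/total strings; cells with no
data are flagged missing, never zero-filled; denominators are
complete-case per cell.  Display rounding is one decimal, half away from
zero, applied at presentation only.

## Synthetic cohort generator

The generator emulates the *descriptive structure* of a two-group HIFU
cohort, not patient-level realism: group sizes 20 (A) and 46 (B);
baseline lesion volumes log-normal with median 68.6 cm³ and log-sd 1.03
(matching an interquartile span of roughly 37–149 cm³); follow-up volumes
driven by normal AVSR draws per group × timepoint (A: 21.5/27.6 %,
B: 21.0/51.0 % at 1 m/3 m, sd ≈ 25–28 %); immediate NPVR normal per group
(A 34.1 %, B 77.1 %, truncated to [0, 100]); clinically effective DII
Bernoulli through a logistic model with per-timepoint baseline log-odds
(1 m: 1.10, 3 m: 1.39, 1 y: 0.54, 3 y: 0.69) and a group-B log-odds shift
of ln 3.69; telephone-follow-up dropout 12 % at 1 y and 36 % at 3 y.
All draws flow through a single explicitly threaded `numpy` generator.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: within-participant correlation between
volumetric response and symptom response (drawn independently; a real
cohort is likely positively correlated), measurement error in axis
lengths, anesthesia effects, adverse events, and any between-timepoint
correlation beyond the shared baseline volume.  Recovery tests (a
binomial-logit refit of effective DII on group averaging ≈3.9 over 200
cohorts of n = 200/group against the 3.69 set-point — the small upward
gap is the expected finite-sample bias of averaging odds ratios — and a
baseline-volume median within 5 % of 68.6 cm³ at n = 2000) validate the
generator's internal consistency, not clinical effect sizes.

## Numerical and design choices

* Bowl tiling refuses `max_subelement` > λ/2 (under-sampled source) and
  rejects non-positive or hemisphere-exceeding geometry.
* The angular-spectrum step is exact for dz = 0 and refuses dz < 0.
* Deterministic throughout: identical inputs give bit-identical fields,
  doses and reports; phantoms are seed-free; cohorts are seeded.
* Desk-scale clinical effect sizes (NPVR/AVSR medians of a 66-participant
  cohort) are **not** reproduced by simulation; the simulation reproduces
  the *directional* premise (B deposits strictly more dose than A on
  well-perfused tissue) and the perfusion sensitivity, which is what a
  treatment-planning comparison can honestly claim at this scale.
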