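# Methods

## Signal model and conversion

The acquisition model is the spoiled-gradient-echo (SPGR) steady state.
With repetition time TR, flip angle θ and baseline signal S(0) averaged over
the pre-contrast frames, the normalised enhancement is

    a(t) = (S(t)/S(0)) · (1 − E0) / (1 − cosθ·E0),    E0 = exp(−R1(0)·TR)

and the relaxation rate follows by inverting the SPGR equation,

    R1(t) = −ln[(1 − a)/(1 − cosθ·a)] / TR.

Pre-contrast R1(0) is fixed per tissue (1000/581, 1000/1172, 1000/1480 s⁻¹
for liver, spleen, blood) rather than mapped per subject; fixed baselines
make the concentration estimate far less noise-sensitive at the cost of a
small per-subject bias. Concentration is then linear in ΔR1 through the
in-situ relaxivity. The registry of constants (`data/constants.csv`) covers
both species and all four agents; any combination outside it raises a
lookup error rather than falling back silently.

Two deliberate policies:

* **Invalid inversions are flagged, not clamped.** Noise near the bolus
  peak can push `a ≥ 1` or the log argument non-positive, where no real
  positive R1 exists. Such samples are marked invalid and excluded from
  filtering windows and fit residuals. Clamping would bias the peak
  downward in exactly the frames that carry the most kinetic information.
* **Negative concentrations are retained.** Flooring at zero would bias
  the residual distribution seen by the fitting objectives; near-zero
  curves (non-hepatospecific agents) would otherwise acquire a positive
  offset.

The intracellular (hepatocyte) curve is the algebraic partition
`Ci = (Ct − ve·Ce)/(1 − ve)` with ve = 0.23 for liver and the spleen-derived
Ce using ve = 0.43. For non-hepatospecific agents the physiologic
intracellular concentration is interpreted as zero; the model is still fit
to the Eq-partition Ci (which hovers near zero under noise) so that the
fitted k1 honestly reports the absence of uptake instead of being defined
away.

## Noise filter

Two centred moving medians (3 and 7 samples, truncated windows at the
series ends) are computed over the full series; the output follows the
short median up to t_a = 300 s, the long median from t_b = 1800 s, and the
pointwise convex blend `m3 + w·(m7 − m3)` with w linear in t between. Both
medians are computed once over the whole series and blended pointwise (the
alternative — re-filtering per segment — differs only within half a window
of the transitions). The blend is written in the `m3 + w·Δ` form so a
constant series passes through bit-exactly. The filter runs in the signal
domain before conversion; the conversion is pointwise and monotone, so
ordering is near-neutral, but signal-domain filtering matches how the
pipeline ingests data.

## Kinetic models

Both forward models are discrete causal convolutions on the uniform frame
grid, with the Δt scaling carried explicitly so the discrete result
converges to the continuous-time solution as Δt → 0 (verified against a
high-order ODE integration for the single-input model and a 100×-finer
quadrature for the dual-input model; both agree to ≤ 0.5 % of the curve
maximum at the test grids). The kernel argument is the lag time tₙ − tₘ.
Pre-bolus frames are kept in the grid with zero input, so model output is
zero there and no start index has to be chosen. The vascular input delay
is fixed at zero: at 7.65–13.5 s frame intervals, the aorta-to-liver transit
time is not resolvable as a free parameter.

Parameters are constrained to [2⁻⁵², 1.0] — s⁻¹ for the rates; the arterial
flow fraction fa is dimensionless and shares the same numeric box. The ±
labels of the biexponential pairs are arbitrary, so reported results are
normalised with the faster decay as (α⁺, β⁺).

## Fitting

The inverse problem is non-convex, so the global search is multistart:
seeded pseudorandom starts (narrow physiologic tier plus a wide tier
spanning 1e-10…1, log-uniform for rates), a bounded local minimizer from
every start, best terminal fit kept. The RNG is re-seeded on every call,
making start lists bit-reproducible. The local optimizer is L-BFGS-B
operating on log10-transformed parameters — the ten-decade wide range is
then well-conditioned — capped at 3000 iterations. Objectives are
`‖r‖²/(2n)` (LSQ) and `‖r‖₁/(2n)` (LAR); LAR is minimised through the
smooth surrogate `|r| ≈ sqrt(r² + δ²)`, δ = 1e-12 mM, far below any
concentration scale in the data, and the reported objective value is always
the exact formula. Residuals are taken at every valid sample, pre-bolus
frames included.

Fitting the single-input model with LSQ to a near-zero curve is known to be
numerically degenerate (flat objective over many decades of k1, k2); the
fitter emits a `DegenerateFitWarning` when the peak |Ci| is below
0.05 mM under that combination, and LAR is the recommended criterion for
non-hepatospecific agents.

`fit_suite` runs the 2×2 grid {LSQ, LAR} × {unfiltered, filtered} per model
and records a skip (with reason) instead of failing when a required curve
is absent — e.g. the spleen outside the field of view precludes the
reference-region model.

## Synthetic studies

The generator emulates the study conditions, not any particular animal:

* **AIF**: gamma-variate bolus (peak 2.5 mM at ~45 s, shape 3) plus a
  biexponential washout tail (fractions 0.16/0.06 of peak, time constants
  240/1800 s), zero before injection and linear in amplitude.
* **Portal vein**: the AIF convolved with a normalised exponential
  transit-time kernel (τ = 12 s), zero bulk delay.
* **Spleen EES surrogate**: the plasma mixture equilibrated with τ = 30 s.
* **Liver**: hepatocyte curve from the single-input forward model (or
  tissue curve from the dual-input model for Berks-truth scenarios), with
  `Ct = ve·Ce + (1 − ve)·Ci`.
* **Rendering**: each compartment mapped to SPGR signal (TR = 5 ms,
  flip 15°, per-ROI baselines of 300–500 a.u.) with additive zero-mean
  Gaussian noise of 0.5 % of baseline by default — the high-SNR limit of
  Rician magnitude noise, appropriate for ROI means over many voxels. The
  analysis-side baseline S(0) is re-estimated from the noisy pre-contrast
  frames, as it would be on real data.

Built-in scenarios pin the frame interval to the dog (7.65 s) and pig
(13.4–13.5 s) protocols over 60-minute sessions, with ground-truth rates
set to the study's reported estimates (dog Gd-EOB-DTPA k1 = 1.0,
k2 = 0.027 min⁻¹; pig Gd-EOB-DTPA k1 = 0.24, k2 = 0.15 min⁻¹; pig Gd-BOPTA
k1 = 0.21 min⁻¹ with k2 = 0.05 min⁻¹ chosen below the pig Gd-EOB-DTPA
efflux). Non-hepatospecific scenarios use k1 = 1e-6 min⁻¹ — near zero but
above the lower bound so optimum-at-bound behaviour is exercised — and a
scenario without a spleen curve exercises the skip path. Default
hematocrit is 0.40 and the default arterial flow fraction used to mix the
synthetic plasma input is 0.25.

What the generator does **not** emulate: respiratory/bulk motion, partial
volume effects, B1 inhomogeneity, intra-ROI kinetic heterogeneity, scanner
drift, or physiologic whole-body clearance. Peak liver concentrations in
the hepatospecific scenarios run high relative to typical patient doses
(several mM), which exaggerates late-phase T1 saturation; the conversion
remains exactly invertible there, but recovery results on synthetic data
bound pipeline correctness, not in-vivo accuracy.

## Numerical choices and edge cases

* Grid uniformity is enforced to 1 % of the frame interval; non-uniform
  series are rejected outright rather than resampled.
* Vascular ROI refinement keeps exactly ⌈n/3⌉ of the radius-1
  (face-connected) dilation, ties broken by descending intensity then
  ascending linear voxel index — deterministic and reproducible.
* Temporal SD projections use the sample (n−1) estimator.
* Convolution inputs must be gap-free, so invalid input samples are
  linearly interpolated for the forward pass only; residuals still exclude
  them.
* Problem sizes in the test-suite recovery checks (reduced multistart
  tiers, 5-seed noise sweeps) were chosen to probe the same optimum the
  full protocol finds on these well-conditioned synthetic curves; the
  acceptance checks use the full 20 + 80 start protocol.

## Known limitations

* The printed-rate recovery scenarios validate the pipeline against its
  own forward models (inverse-crime setting); they demonstrate estimator
  correctness and noise robustness, not model adequacy for real livers.
* fa in the dual-input model is weakly identified when the portal curve is
  a dispersed copy of the arterial curve — fitted fa values under noise
  drift above the generating value while the impulse-response kernel stays
  accurate, echoing the wide fa spreads reported in the imaging literature.
* LAR is handled by smoothing, not by a true non-smooth solver; with
  δ = 1e-12 mM the difference is far below every tolerance used here.
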