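# Methods

This note records the scientific and numerical choices behind `qperf`:
what is modelled, what the defaults mean, what the digital phantom does
and does not emulate, and where the open design decisions were settled.

## Signal model

Saturation-recovery (SR) imaging resets longitudinal magnetization every
heartbeat; the acquired signal therefore encodes the instantaneous T1,
which gadolinium shortens in proportion to its concentration
(1/T1 = 1/T1_0 + r1·CA).  `sr_gre_signal` iterates the magnetization
explicitly — saturation scaled by a configurable efficiency (default 1.0;
the >95% protocol bound is a validator rule, not a model default), free
recovery over TD, then one flip/recover step per k-space line up to the
centre line.  A bSSFP variant adds T2 decay of the transverse component
with alternating RF phase and an α/2 catalyzation; off-resonance,
slice-profile and water-exchange effects are not modelled.  The fixed T2
for bSSFP conversion defaults to 45 ms (myocardium-like).

Inversion goes through a tabulated dictionary (default 1 ms steps over
50–3000 ms, linear interpolation between nodes; construction fails if the
signal is not strictly decreasing in T1, rather than inverting an
ambiguous table).  Signals outside the table are clamped and flagged for
QC — never extrapolated.

M0 normalization uses the proton-density (PD) lead-in frames:
M0 = PD/sin(α_PD) per pixel (a smoothed "surface" variant is available;
neither is privileged).  Because PD and SR frames see the same coil
sensitivity, the pixelwise normalization cancels coil bias exactly.
Conversion uses fixed population baseline T1 values (defaults 1600 ms
blood, 1200 ms myocardium, 3T-like, overridable); any per-pixel mismatch
between the assumed and true baseline produces a constant concentration
offset that the subsequent baseline correction removes exactly, which is
why baseline correction is applied after conversion as well.

T2* correction fits S(TE) = S0·exp(−TE/T2*) log-linearly over the
available echoes (exact for two echoes); non-decaying signals are
reported as T2* = ∞ with a flag.

## Preprocessing

Order: register → coil-correct → baseline-correct (configurable).
Registration is translation-only.  Because contrast passage defeats
naive inter-frame correlation, the estimator first masks out dynamic
pixels (temporal SD of the SR frames above 5% of its maximum, dilated),
finds each frame's integer shift by exhaustive normalized cross-
correlation of the static content over ±8 px, and then refines to
subpixel precision with phase correlation of high-passed frames after
integer alignment; refinements ≥1 px (correlation failures) or <0.1 px
(numerical noise) are discarded.  Coil correction offers the quadratic
surface fit (fitted to the brightest Otsu tissue class with one
outlier-rejection pass, because mixing proton-density classes folds
anatomy into the bias estimate) and the simpler pixelwise PD division.
Baseline nulling subtracts the mean of the pre-contrast SR frames
(frames before AIF arrival − 1 by default) and applies equally to signal
or concentration curves.  Spatial filtering (Gaussian/median) exists but
defaults to off and refuses AIF series; temporal filtering is
deliberately not implemented.

## AIF handling

The LV blood pool is located on the temporal-SD map (Otsu threshold),
candidates ranked by early-and-bright enhancement, and the winner eroded
to exclude papillary muscle and endocardial partial-volume pixels.  The
AIF is the mask-mean curve (PD frames excluded); a spread of per-pixel
peak times beyond 3 samples flags probable tissue contamination.
Arrival detection offers the triangle method (maximal distance from the
foot-to-peak chord; amplitude-invariant) and an upslope-line fit over
samples bracketing the 20–80% band (which lands ~1 sample late on convex
feet — the triangle method is the default).  Blood-to-plasma conversion
divides by (1 − hematocrit), default 0.42.  Dual-bolus studies are
supported by rescaling a diluted pre-bolus AIF by 1/dilution (default
10%) and realigning its arrival to the main bolus.

## Kinetics

All estimators share a cached trapezoid-rule convolution engine that
evaluates impulse responses on a uniform fine grid (8× the shortest
sampling interval) and resamples at the measurement times, so irregular
RR grids are handled directly.  Flows are mL/min/mL internally;
reported MBF divides by tissue density 1.05 g/mL and, under the default
blood-flow convention, by (1 − Hct).

* **Fermi** — first-pass constrained deconvolution; the linear
  parameters are profiled over a 12-point (μ, k) seed grid before
  Levenberg–Marquardt.  The optional interstitial offset term is off by
  default: the short first-pass window cannot separate it from the decay
  parameters and letting it float biases I(0) low by tens of percent.
  MBF is read as I(0) excluding the offset.
* **2CXM** — analytic bi-exponential residue from the closed-form
  eigen-decomposition of the two-compartment system; coarse-to-fine
  fitting (8 points/parameter over F_p∈[0.1,6], v_p∈[0.01,0.2],
  v_e∈[0.05,0.5], PS∈[0,2]; the grid predictions are cached per AIF,
  then Nelder–Mead).  When a restricted no-exchange (PS = 0) submodel
  fits as well, it is preferred (parsimony) and flagged, which resolves
  the v_e→0/PS→∞ degeneracy.  Boundary-pinned parameters are flagged.
* **Patlak** — linear regression of C_t/C_a on ∫C_a/C_a over the early
  window; negative slopes are clamped to zero and flagged.
* **Tikhonov** — the discretized convolution uses trapezoid quadrature
  weights (rectangle weights underestimate I(0) by ~2× at heartbeat
  sampling); λ = 0 solves the triangular system directly when the AIF
  starts non-zero and otherwise raises with advice to regularize.

First-pass cropping runs from the foot of the AIF upslope (one sample
before the detected arrival, retaining the sub-sample onset ramp) to the
earlier of 30%-of-peak decay or the pre-recirculation minimum.  The
per-pixel arrival search refits over delayed copies of the AIF and keeps
the smallest-residual result, ties to the earliest arrival.

Known limitation: Fermi deconvolution on 2CXM-like tissue underestimates
flow increasingly above ~2 mL/min/mL at 1-s sampling (≈7% at
1 mL/min/mL, ≈30% at 4), a property of the estimator, not a bug; the
matched 2CXM fit is unbiased there and is the default for MPR work.

## Digital phantom

The phantom renders dual-sequence stress/rest studies with complete
ground truth.  The AIF is a gamma-variate (defaults: onset 8 s, α 3,
β 1.5 s, peak 4 mmol/L — chosen to drive the SR signal well into its
nonlinear range at a clinical-dose-like peak; recirculation as a delayed
scaled copy, fraction 0.15 at 25 s).  Tissue curves are forward
convolutions of the chosen residue model (default 2CXM with rest
F_p = 1.0 mL/min/mL, v_p = 0.08, v_e = 0.2, PS = 0.5; stress scales F_p
only).  Frames are rendered through the same Bloch recursion the
conversion inverts, with: 1–4 PD lead-in frames; a positive quadratic
coil-bias field; a smooth random background texture (chest-wall-like
static anatomy that gives registration something to lock onto);
Rician-like noise (complex Gaussian → magnitude, SD as a fraction of the
PD level, default 0 — noise levels are set explicitly per experiment);
sinusoidal or per-frame in-plane translation; and trigger times from an
RR schedule that may contain missed beats.  Identical seeds give
byte-identical studies.

Not emulated: through-plane motion, dark-rim artifacts, k-space
undersampling artifacts, cardiac-phase changes, non-rigid deformation,
realistic thoracic anatomy.  Tests passing on this phantom therefore
demonstrate the correctness of the numerical chain under its own
assumptions, not clinical performance on patient data.

## Maps, burden, protocol rules

Quantification is per pixel (the whole point of perfusion CMR's spatial
resolution); failed pixels are flagged, never interpolated.  MPR divides
stress by rest MBF with a rest floor of 0.1 mL/min/g.  AHA-16 labelling
uses 6/6/4 angular sectors from the anterior RV insertion point.
Ischemic burden is area-weighted percent of myocardium below threshold
(segment counts are also reported for the 2-of-16 ≈ 12.5% rule of
thumb); apical pixels within 1 px of the mask boundary are excluded from
burden statistics.  Abnormality thresholds (stress MBF < 1.5 mL/min/g,
MPR < 2) are explicitly non-normative configuration values.  The
protocol validator checks: myocardial TS ≤ 130 ms, AIF TS < 30 ms,
acquisition window < 120 ms, saturation efficiency > 95%, in-plane
resolution ≤ 2.5 mm, slice thickness ≤ 10 mm, ≥ 3 slices; missing
parameters are "unverifiable", not violations.

## Quality control

Computable counterparts of the standard review checklist: RR intervals
(missed beat when an interval exceeds 1.75× the running median; critical
inside the AIF/myocardial upslope), AIF shape (flat-top saturation when
≥3 consecutive samples sit within 1% of the peak; smoothness as the
total-variation fraction removed by a Savitzky–Golay fit; low SNR below
peak/baseline-SD of 10), baseline blood-pool enhancement (remnant
contrast when the pre-contrast LV/myocardium ratio exceeds 1.3),
residual post-registration motion (>1 px), map-vs-image wall-thickness
agreement, and per-segment fit-failure fractions (segments above 20%
excluded).  All thresholds are package choices, logged in every report;
the guidance they implement mandates the checks but quantifies none of
them.

## Problem sizes

Tests and the acceptance script run on reduced matrices (36–48 px,
single slice, 50 frames) chosen so the full suite and script each
complete in a few minutes while leaving every algorithmic path —
including pixel-wise fitting over hundreds of pixels — fully exercised.
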