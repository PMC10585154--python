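# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter.

## Measurement chain

### Phase-contrast flow and CBF

Pixel phase maps linearly to through-plane velocity, v = venc·φ/π, with
venc = 100 cm/s by default. Vessel flow is the ROI mean velocity times
the ROI area (a pixel belongs to a vessel when its mask value ≥ 0.5; no
sub-pixel area correction — the simplest reproducible rule). CBF is the
summed inflow of the two internal carotids and the basilar artery
normalized to brain mass, with tissue density fixed at 1.05 g/ml
(configurable; the density converts ml of parenchyma to g). Cardiac
gating is not modeled: a single image is treated as the time-averaged
velocity. Aliasing correction is single-wrap only ("shift" policy): a
pixel whose velocity opposes the expected flow direction by more than
venc/2 is assumed to have wrapped once; velocities needing more than
one wrap raise an error, since a single phase sample cannot
disambiguate them. Vessel tilt relative to the slice is not corrected;
for near-axial feeding vessels the cos-θ area/velocity factors cancel
to first order.

Discretization: integrating a parabolic profile by pixel counting is
accurate to well under 2% for vessel radii ≥ 4 pixels because the
velocity vanishes at the wall, so boundary pixels contribute little.

### Susceptibility-based oximetry and CMRO₂

Deoxygenated blood in a long cylindrical vessel at angle θ < 54.7° to
B₀ shifts the intravascular field by
ΔB = ½·Δχ_do·Hct·(1−SvO₂)·B₀·(cos²θ−⅓), giving an inter-echo phase
offset Δφ = γ·ΔB·ΔTE relative to adjacent tissue. Defaults:
Δχ_do = 4π×0.27 ppm (SI) per unit hematocrit, θ = 0 (the sagittal sinus
runs nearly parallel to B₀ in the supine position), TE 8.07/17.77 ms at
3 T — all configurable. The susceptibility offset of fully oxygenated
blood relative to tissue is neglected; this is a small systematic
approximation common to phase-referenced oximetry. Per-pixel inter-echo
differences are rewrapped into (−π, π], which undoes single 2π wraps
automatically; an ROI whose wrapped differences are mutually
inconsistent (circular spread > π/2) raises instead of silently
averaging garbage.

Hematocrit follows from venous hemoglobin via the monomer molar mass
(16,114 g/mol) and ≈ 0.03 hematocrit per g/dl. Hemoglobin is accepted
in mmol/l of monomer (the Danish clinical convention) with a g/dl
conversion helper. CMRO₂ = Hgb·CBF·(SaO₂−SvO₂) assumes one O₂ per
monomer and neglects dissolved O₂ (~2% of arterial content). SaO₂ is
taken from pulse oximetry averaged over the oximetry acquisition
window.

### MRS lactate

Quantification scales the fitted lactate methyl amplitude by the voxel
water amplitude, corrects both to TE = 0, multiplies by the voxel water
concentration (tissue fractions × compartment water content ×
55,510 mmol/l) and by the water/lactate proton ratio 2/3. Literature
constants, all in one editable table: T₂ water 90/70/500 ms
(GM/WM/CSF), T₂ lactate 240 ms, water contents 0.78/0.65/0.97. The
exact literature values behind any given study are not uniquely
recoverable; these sit in the middle of the 3 T range and are flagged
as assumptions. T₁ saturation is omitted (TR 3,000 ms leaves a few
percent residual saturation that largely cancels in the ratio).
Concentrations are "wet" per liter of water-visible tissue; no
CSF-exclusion renormalization is applied because tissue composition is
instead carried as a statistical covariate.

### Volumetry

Volumes are voxel counts times voxel volume (0.70³ mm³ default);
ICV = all nonbackground labels (ventricular and sulcal CSF are not
distinguished), TBV = GM + WM, BPF = TBV/ICV. Segmentation itself is
upstream of this package: label maps are inputs.

## Statistics

The saturation-response model is a linear mixed model with fixed
effects for group, SaO₂ (in percentage points, uncentered; slopes are
per % saturation), their interaction, sex (0/1 indicator) and age, and
a random intercept per subject, estimated by REML. The random intercept
absorbs between-subject baseline differences, so the fixed SaO₂ terms
test only the response to desaturation; the gray-matter fraction of the
MRS voxel is added for lactate models. Groups are treatment-coded
against healthy controls, so each interaction coefficient is (group
slope − healthy slope): with a negative healthy slope, a positive
interaction means a blunted rise under desaturation.

**Inference.** Between-subject heterogeneity of the true response
slopes makes the within-subject changes heteroscedastic in proportion
to each subject's desaturation, which the random-intercept working
model does not represent. Model-based Wald tests are then
anticonservative (measured ~0.08 type-I error at nominal 0.05 under
the default generator). Fixed-effect inference therefore uses
bias-reduced cluster-robust covariance (CR2) with Satterthwaite degrees
of freedom, the Bell–McCaffrey small-sample treatment; measured
calibration is 0.050 type-I error and 0.950 CI coverage over 400
simulated cohorts each. A random-slope model is not an alternative
here: with exactly two observations per subject its covariance is
unidentified, and it measured worse (0.087/0.91). `robust=False`
restores model-based Wald inference. A perfectly noise-free fit makes
REML degenerate; that case falls back to subject-fixed-effects OLS,
which gives the identical within-subject slopes exactly.

Baseline-shift invariance (adding any per-subject constant to both
conditions) holds exactly only in the infinite intercept-variance
limit; finite partial pooling permits shifts of order 1%, and the tests
assert the property at 2% tolerance.

Response ratios are two-point slopes (Y_hyp − Y_norm)/(SaO₂_norm −
SaO₂_hyp), positive when the variable rises under desaturation, and are
defined only for positive desaturation. Group differences and
volume-on-response associations are covariate-adjusted OLS with Wald
CIs; the association export includes Frisch–Waugh partial-regression
residuals for plotting. The power operation is the two-sample
normal-approximation n = ⌈2σ²(z₁₋α/₂+z_power)²/δ²⌉ with a floor of 2
and an inverse (`detectable_difference`); the detectable difference is
an explicit parameter, never hard-coded. No multiple-testing correction
is applied anywhere.

## Synthetic-data generator

The generator emulates a three-group hypoxic-challenge cohort: group
sizes 19/22/11, sex splits 12/19, 9/22 and 7/11 male, ages
45.0±14.0 / 47.3±12.9 / 56.0±10.8 y, hemoglobin 8.9/8.9/8.6 mmol/l,
resting CBF 42.0/41.3/39.3 ml/100 g/min, resting CMRO₂
124.8/130.9/117.6 μmol/100 g/min, resting lactate 0.53/0.48/0.42
mmol/l, gray/white-matter volumes 632/478, 628/482 and 585/441 ml with
total brain volumes 1139/1139/1053 ml and parenchymal fractions
0.78/0.78/0.75. Normoxic SaO₂ is drawn at 98±1%, the hypoxic plateau at
78±4%. Desaturation traces approach the plateau exponentially (time
constant 120 s) with temporally smoothed noise; end-tidal CO₂ falls
~5 mmHg and heart rate rises ~8 bpm on the same time scale.

Only the structurally asserted links are modeled; everything else is
drawn independently from the group marginals:

* **Response slopes.** Each subject has true slopes of lactate, CBF and
  CMRO₂ versus SaO₂ (group mean + individual deviation). Group anchors:
  healthy lactate −0.012 mmol/l per %, chosen so the group contrasts
  equal the reported interactions (albuminuria −0.004, giving
  alb−healthy = +0.008 and alb−no-alb = +0.006 mmol/l/%); CBF −0.40
  (healthy and no-albuminuria) and −0.20 (albuminuria); CMRO₂ 0
  everywhere (oxygen metabolism maintained under moderate hypoxia).
  Absolute per-group slopes are assumptions — only the contrasts are
  pinned. The between-subject lactate-slope sd (0.006) is set so the
  implied precision of the volume-on-response regression matches the
  reported interval widths, which implies a wide individual spread of
  glycolytic responses.
* **Volume–response link.** Gray and white matter are anchored at the
  healthy means and linked to the subject's true lactate response
  ratio at 1,405 and 2,407 ml per ratio-unit (total 3,812), plus age
  effects and a sex effect (40/35 ml, male−female). Age slopes are
  derived from the calibration identity that places the
  albuminuria-group GM/WM means on their configured values given the
  link and demographics (−3.27 and −1.63 ml/y). Group volume
  differences are thus carried entirely by age and the response link —
  there are no per-group volume intercepts — so the volume ~ ratio
  regression adjusted for sex and age recovers the configured link
  without bias. The cost is that the no-albuminuria group's volume
  means land ~1–2% off their table values; the calibrated groups
  (healthy, albuminuria) are exact in expectation.
* **TBV bookkeeping.** The tabulated total brain volumes exceed GM+WM
  by ~27–29 ml, so TBV = GM + WM + a small unsegmented-parenchyma
  component with those group means; label-map volumetry, which only
  sees GM/WM/CSF, reports TBV = GM + WM exactly. ICV follows from TBV
  and a drawn parenchymal fraction.
* **Physiological consistency.** The per-condition oxygen extraction
  fraction CMRO₂/(Hgb·CBF) is constrained to [0.10, 0.50] by redrawing
  the CMRO₂ tail, keeping the implied venous saturation well inside
  (0, 1) and the oximetry phantom inside a single phase wrap. This
  truncates under 1% of draws.
* **Measurement noise.** Per-condition noise (lactate 0.01 mmol/l, CBF
  1.5, CMRO₂ 6.0 units) is kept small relative to the between-subject
  spread; the resting-value biological sds are reduced accordingly so
  the marginal sds stay at the table values. Larger condition-level
  noise would attenuate the volume-on-measured-ratio regression below
  the generating link (errors-in-variables), which is worth remembering
  when comparing to real data, where single-measurement MRS noise is
  substantially larger.

What passing tests therefore show: the quantification operations invert
their forward models exactly, and the statistical layer recovers the
generating parameters without bias *under this generator's structure* —
independent marginals, linear links, Gaussian noise, no motion or
drift, no segmentation error, and fitted amplitudes rather than
spectra. They do not certify performance on real spectra, real phase
maps with background gradients, or FreeSurfer outputs.

## Problem sizes and numerical choices

Calibration checks average 200 replicate cohorts; recovery simulations
use 500; the type-I-error property uses 1,000 — sizes at which the
Monte-Carlo standard error of each checked mean is a few tenths of a
percent to ~1% of its target. Phantom grids are 64×64 (oximetry) and
48 mm FOV at 0.75 mm pixels (flow). Phase wrapping uses (−π, π]
throughout; the SBO forward/inverse roundtrip is exact to 1e-10; the
minimum of a cohort-averaged desaturation trace is read off a 30-s
smoothed curve to avoid the extreme-value bias of a raw minimum over
noisy samples. Seeds propagate from a single integer through
`numpy.random.default_rng`; every generator is bit-reproducible and
every pipeline output embeds the seed and a configuration hash.

## Known limitations

No k-space or pulse-sequence simulation; no spectral fitting (fitted
amplitudes are the interface); no background-field or eddy-current
correction; single-wrap aliasing handling only; no vessel-tilt
correction; volumes and physiology are cross-sectionally linked, not
longitudinally modeled; the no-albuminuria group's volume means are
approximate by design (see above).
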