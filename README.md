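# cerebroquant

Quantitative-MRI measurement chain and statistics for hypoxic-challenge
studies of cerebral physiology — built for case–control designs that ask
whether cerebrovascular reactivity or cerebral glycolytic capability is
impaired, and whether such impairment tracks brain atrophy.

The package implements, as tested and composable stages:

* **Phase-contrast flow → CBF.** Velocity-encoded phase images map
  through-plane blood velocity as v = venc·φ/π. Vessel flow is the mean
  ROI velocity times cross-sectional area; total inflow over the carotid
  and basilar arteries, normalized to brain mass (density 1.05 g/ml),
  gives CBF in ml/100 g/min. Single-wrap aliasing correction included.
* **Susceptibility-based oximetry → Fick CMRO₂.** The inter-echo phase
  offset of the sagittal sinus relative to adjacent tissue follows the
  infinite-cylinder model Δφ = ½·γ·B₀·ΔTE·Δχ_do·Hct·(1−SvO₂)·(cos²θ−⅓);
  inverting it yields SvO₂, and CMRO₂ = Hgb·CBF·(SaO₂−SvO₂) with Hgb in
  mmol/l of monomer (one O₂ site per monomer).
* **Water-referenced MRS lactate.** The fitted lactate amplitude is
  scaled by the voxel water signal, with both decay-corrected to TE = 0
  using literature T₂ values, partial-volume water content per
  GM/WM/CSF compartment, and the 2/3 proton-count ratio.
* **Volumetry.** Voxel-count volumes and the brain parenchymal fraction
  (BPF = TBV/ICV) from segmentation label maps.
* **Statistics.** Per-subject response ratios ΔY/ΔSaO₂; linear mixed
  models Y = β₁·group + β₂·SaO₂ + β₃·group·SaO₂ + β₄·sex + β₅·age + u
  with a random intercept per subject and cluster-robust (CR2 +
  Satterthwaite) inference; covariate-adjusted group contrasts;
  volume-on-response regressions with partial-regression exports; a
  two-sample normal-approximation power calculation.
* **Synthetic data.** A seeded generator produces three-group cohorts
  (healthy n=19, diabetes without albuminuria n=22, with albuminuria
  n=11) with calibrated demographics, brain volumes, paired
  normoxia/hypoxia physiology, desaturation traces bottoming near 78%
  SaO₂, and image-level phantoms (flow, oximetry, MRS, label maps) that
  carry analytic ground truth.

## Worked example

```python
>>> from cerebroquant import cmro2_fick, hct_from_hgb, svo2_from_phase
>>> from cerebroquant.sbo import SboAcquisition, BloodModel
>>> acq = SboAcquisition(b0=3.0, te1=8.07, te2=17.77)
>>> svo2, _ = svo2_from_phase(1.33, acq, BloodModel(hct=0.42))
>>> round(svo2, 3)
0.64
>>> round(cmro2_fick(8.9, 42.0, 0.98, 0.98 - 0.334), 1)
124.8
```

A 1.33 rad inter-echo phase offset at 3 T (ΔTE 9.7 ms, Hct 0.42, vessel
parallel to B₀) corresponds to 64% venous saturation; with hemoglobin
8.9 mmol/l, CBF 42 ml/100 g/min and an arteriovenous saturation
difference of 0.334 the Fick principle gives a CMRO₂ of
124.8 μmol/100 g/min — a typical healthy-adult value.

Full pipeline from the shell:

```bash
cerebroquant run --seed 1 --out run1/
# -> run1/summary.json, cohort tables, per-subject quantification,
#    mixed-model and group-difference coefficient tables
```

The summary reports, among other things, the albuminuria-vs-healthy
lactate interaction (≈ +0.008 mmol/l per % SaO₂ under the default
calibration — a blunted lactate rise under desaturation) and the
volume–response association (≈ 3,800 ml of total brain volume per unit
lactate response ratio).

## Layout

```
src/cerebroquant/
  config.py      cohort configuration + calibrated defaults
  synthetic/     cohort, physiology-trace and phantom generators
  pcm.py         phase-contrast flow quantification
  sbo.py         susceptibility oximetry + Fick CMRO2
  mrs.py         water-referenced lactate quantification
  volumetry.py   label-map volumetry
  stats.py       mixed models, response ratios, regressions, power
  pipeline.py    end-to-end orchestration
  cli.py         `cerebroquant` command-line interface
docs/methods.md  model assumptions, defaults and design notes
```
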