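# Methods

## The measurement model

The package analyzes segmented nerve voxels from high-resolution MR
neurography of the lower extremity. Each voxel record carries a
T2-weighted signal intensity and its anatomical address: subject, side
(L/R), nerve territory (tibial or peroneal fascicles of the sciatic nerve
and their distal continuations), and a 1-based slice index ordered
proximal → distal (tibial 1–140, thigh to tibiotalar joint; peroneal 1–60,
thigh to fibular head — peroneal branches distal to the fibular head are
excluded as not reliably segmentable). Within one mid-to-distal thigh slab
(slices 36–70 of the tibial axis in the synthetic geometry, i.e. the
second 35-slice block of four) a dual-echo acquisition provides two
intensities per voxel at TE₁ = 12 ms and TE₂ = 73 ms.

### Lesion-voxel classification

Raw T2-weighted intensities are not comparable across slice positions,
coils or subjects, so classification is referenced to the nondiabetic
control population. For every stratum — (slice, territory, side) — the
control intensities are binned into 100 equal-width bins spanning their
observed range; the center of the bin with the maximal raw count (lowest
bin on ties) is the stratum reference. Every voxel is divided by its
stratum reference, so the control mode maps to 1.0 by construction, and
`is_lesion = normalized > threshold` with a strict inequality at the
default threshold 1.5.

Design choices here were genuinely open:

* *Normalization semantics.* Dividing voxel intensities by the peak-bin
  center (rather than dividing bin counts) makes the normalized value a
  dimensionless multiple of the control mode and the threshold "1.5× the
  control tissue mode". This is the reading under which a threshold on
  normalized signal intensity is well defined.
* *Tie-break.* Lowest-intensity bin on tied counts: deterministic, and
  conservative in the sense that a lower reference inflates normalized
  values, so any bias shows up as extra lesions in the self-consistency
  tests rather than silently vanishing lesions.
* *Degenerate strata.* A constant-intensity stratum gets a single-support
  histogram whose peak is that value.
* *Threshold sweep.* The operator-independent threshold choice maximizes
  the one-way ANOVA F statistic of per-subject total lesion burden across
  the four severity groups over a grid (default 1.05–3.00 in steps of
  0.05, lowest threshold on ties). Grid points where every count is zero
  contribute F = 0.

### Spatial mapping

Lesion calls are counted per slice within each side, then combined across
sides — by default the mean of left and right, so per-slice figures are
per-leg counts; a sum rule is available since side handling is a
convention, not a measurable. Regional burdens are arithmetic means over
the inclusive windows 21–46 (proximal, the region of the lesion maximum)
and 95–120 (its distal counterpart), 26 slices each; totals are sums over
the full axis. Nerve caliber is voxel count × 0.42 mm³ per slice (0.4 ×
0.3 mm in-plane × 3.5 mm slice thickness; the 0.35 mm interslice gap is
not added because caliber is defined as total voxel volume).

### Two-point relaxometry

With two echoes the mono-exponential decay is inverted exactly:
`T2app = (TE₂−TE₁)/ln(SI₁/SI₂)` and `ρ = SI₁·exp(TE₁/T2app)`. ρ is in
arbitrary units consistent within a run; no absolute calibration is
attempted. Inversion is voxel-wise followed by averaging over the slab
(an ROI-mean-first variant would commute only in the noiseless limit).
Voxels with SI₁ ≤ SI₂ have no defined decay and are excluded and counted
in QC flags. Under Rician (magnitude) noise the per-voxel ρ estimator is
biased upward at low SNR; the test suite quantifies this on fixtures
instead of asserting unbiasedness.

### Statistics

* One-way ANOVA uses the classical between/within decomposition; pairwise
  group contrasts are two-group F tests with Holm step-down adjustment
  (via statsmodels, cross-checked against a brute-force step-down in the
  tests).
* The repeated-measures design (group between subjects × location within,
  two levels) is computed from its exact two-level reduction: the group
  main effect is the one-way ANOVA of per-subject means, the interaction
  is the one-way ANOVA of proximal−distal differences, and the location
  main effect tests the grand mean difference against the same
  within-subject error, all with split-plot denominator df (1 or g−1,
  N−g). The identity "interaction F = difference-score ANOVA F" is used
  as a test oracle, plus a cross-check against `pingouin.mixed_anova` on
  balanced data. No sphericity correction is needed with a two-level
  within factor.
* Ordinal severity (control < no-DPN < mild/moderate < severe, all four
  levels by default; a diabetic-only analysis just subsets the input) is
  modeled by proportional-odds logistic regression fit by maximum
  likelihood (statsmodels `OrderedModel` on ρ/100, so the coefficient is
  directly the log-odds per 100 proton spins). Wald 95% CI; complete
  separation is flagged and the CI reported unbounded. Predicted
  cumulative probabilities P(severity ≥ level | ρ) are returned on a ρ
  grid.
* ROC: the empirical AUC (equal to the normalized Mann–Whitney U;
  pair-counting oracle in the tests), a stratified bootstrap percentile
  CI (default 2000 replicates, seeded), and sensitivity/specificity at
  named cutoffs with the positive rule `score ≥ t`. The positive class is
  symptomatic DPN (mild/moderate + severe), negatives are nondiabetic
  controls.
* Backward stepwise OLS drops the least significant covariate until all
  retained p ≤ 0.05 (removal threshold a convention; `threshold=1`
  returns the full model). Exactly collinear columns are removed with a
  warning before stepping.

## The synthetic-cohort generator

The generator emulates the cohort structure the analysis assumes, so every
stage can be tested against planted ground truth without any image data.

* **Groups and sizes:** control 25, diabetes-no-DPN 15, mild/moderate 25,
  severe 10.
* **Lesion rates** (expected lesion voxels per slice per leg): proximal
  anchor (slices 21–46) 18/21/35/57 and distal anchor (95–120) 8/8/12/22
  for the four groups; piecewise-linear interpolation between the anchor
  regions and constant extrapolation outside, so the window means equal
  the anchors exactly. Per-slice planted counts are Poisson with the
  interpolated mean, truncated at the slice's voxel count. The
  configured rates are defined on the tibial axis; peroneal rates are
  scaled by the group's peroneal/tibial caliber ratio so the per-voxel
  lesion fraction is territory-invariant. Whether published per-slice
  counts are per leg or summed over legs is a convention; both are
  exposed (`lesion_rate_scope`), default per-leg, matching the side-mean
  aggregation downstream.
* **Intensities** (arbitrary units): background voxels draw from a normal
  (mean 100, SD 10) truncated at ±3 SD; lesion voxels draw from a
  narrower truncated normal centered at 1.8 × the background mode
  (SD 5). The truncation bounds guarantee that, in the noiseless default,
  background stays below 1.3× and lesions above ~1.6× the mode, so
  threshold-1.5 classification reproduces the planted flags exactly —
  that is the point of the noiseless regime, and it is what the
  "oracle equivalence" tests exploit. The narrower lesion spread keeps
  the control histogram's modal bin on the background peak even though
  controls carry lesion voxels too.
* **Spin density:** one subject-level ρ draw per subject from the group
  distribution — means 288 (control), 323 (no-DPN), 365 (mild/moderate),
  360 (severe); SDs recovered from published standard errors as
  SEM·√n: 67.0, 55.77, 76.0, 72.42. Lesion voxels carry ρ elevated by a
  factor 1.25 at unchanged T2, encoding the study's finding that lesion
  conspicuity is a density effect, not a T2 effect. Nerve T2 defaults to
  60 ms — no group T2 values are published (only their non-significance),
  so this is a convention from typical peripheral-nerve T2 at 3 T, not a
  study fact.
* **Caliber:** mean segmented voxels per slice by territory and group
  (tibial 125.7/143.8/148.8/177.1; peroneal 56.0/56.2/58.6/69.5 —
  published mm³ means divided by 0.42 mm³), with a mean-preserving linear
  taper of ±30% from slice 1 to the last slice emulating anatomical
  narrowing; per-slice counts are Poisson draws.
* **Covariates:** normal draws with group means/SDs (SEM·√n) and
  Bernoulli flags with group prevalences from the published cohort table;
  scores are clipped at 0 but kept continuous (integer rounding would
  bias small group means). Controls' metabolic covariates (HbA1c, BMI)
  are population-typical conventions because the cohort table reports
  only the diabetic columns.
* **Noise:** none by default; additive Gaussian or Rician optional. The
  generator does not model motion/bias-field artifacts, partial volume,
  spatially correlated noise, within-nerve fascicle texture, or real
  anatomical geometry — so passing tests demonstrate correctness of the
  estimators under the stated statistical structure, not robustness to
  real-world image degradation.

Determinism: a single `numpy` Generator seeded from the config drives all
draws in a fixed iteration order; identical config + seed gives
byte-identical tables.

## Problem sizes in the shipped checks

The acceptance computations use the study-scale conditions: the ordinal
recovery fits n = 5000 subjects with the published effect (OR 2.9 per 100
spins) planted; the ROC surface samples 10⁴ subjects per class from
normal models with the published moments; the lesion-burden recovery runs
100 seeded cohorts of 10 severe + 25 control subjects, tibial territory
only (the proximal/distal windows are defined on the tibial axis, so
peroneal voxels never enter those figures). The unit-test fixtures use a
down-scaled cohort (22 subjects, ~30-voxel calibers) with
correspondingly tightened intensity spreads so the thin control strata
still pin the histogram mode; the full-scale margins are much wider.

## Known limitations

* The two-point inversion is exact only for mono-exponential decay; no
  multi-echo fitting, B1/stimulated-echo correction, or absolute
  water-content calibration.
* The location main effect in the split-plot ANOVA uses the weighted
  grand mean of the differences; with unbalanced groups an unweighted
  (type-III-style) variant would differ slightly. The interaction and
  group tests are unaffected.
* Real segmentation masks and the image-ingestion path (NIfTI + label
  mask) assume the axial axis is the slice axis; the proximal→distal
  direction must be declared by the caller because NIfTI axis direction
  is scanner-dependent.
* Contrast-to-noise analysis of spinal-nerve/plexus ROIs and nerve
  conduction endpoints are out of scope; electrophysiological covariates
  exist in the generator only as metadata.
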