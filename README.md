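# nervequant

Quantitative MR neurography of lower-extremity peripheral nerves for
diabetic polyneuropathy (DPN). The package implements an
operator-independent analysis of segmented nerve voxels — tibial and
peroneal territories followed from the proximal thigh (slice 1) to the
ankle (tibial slice 140) or fibular head (peroneal slice 60) — for
cross-sectional cohorts spanning four ordinal severity groups:
nondiabetic controls, diabetes without DPN, mild/moderate DPN, and severe
DPN. It is aimed at imaging scientists who have per-voxel intensity tables
(or NIfTI volumes plus label masks) and want reproducible lesion burdens,
spin-density maps and severity statistics, and at methodologists who want
to exercise the whole pipeline on synthetic cohorts with known ground
truth.

## What it computes

**Lesion-voxel classification.** For every stratum (slice position × nerve
territory × side), the control population's nerve-voxel intensities are
histogrammed into 100 equal-width bins; the center of the modal bin is the
stratum's reference intensity. Every voxel is normalized by its stratum
reference, so the control mode maps to 1.0, and a voxel is a *lesion
voxel* when its normalized intensity exceeds the binary threshold
(default > 1.5, selectable by an F-statistic threshold sweep).

**Proximal-to-distal mapping.** Lesion counts are profiled per slice,
side-aggregated, and averaged over the proximal window (slices 21–46) and
its distal counterpart (slices 95–120). Nerve caliber is the total
segmented voxel volume per slice (voxel 0.4 × 0.3 × 3.5 mm³ → 0.42 mm³).

**Dual-echo relaxometry.** On the thigh slab acquired at two echo times
(TE₁ = 12 ms, TE₂ = 73 ms), the mono-exponential decay
SI(TE) = ρ·exp(−TE/T2app) is inverted voxel-wise:

    T2app = (TE₂ − TE₁) / ln(SI_TE₁ / SI_TE₂)
    ρ     = SI_TE₁ / exp(−TE₁ / T2app)

ρ (proton spin density) is the signal extrapolated to TE = 0; non-decaying
voxels are excluded and counted, not clipped.

**Group statistics.** One-way ANOVA of total lesion burden with
Holm-corrected pairwise contrasts; split-plot repeated-measures ANOVA
(group × location); proportional-odds ordinal regression of severity on ρ
reported as an odds ratio per 100 proton spins; ROC analysis (AUC with
stratified bootstrap CI, sensitivity/specificity at named cutoffs using
the `score ≥ t` rule); and backward stepwise OLS of ρ on clinical
covariates.

**Synthetic cohorts.** `nervequant.generate_cohort` builds cohorts with
the full data structure above — group-dependent regional lesion rates
(control 18, no-DPN 21, mild/moderate 35, severe 57 lesion voxels per
proximal slice; 8/8/12/22 distally), group-dependent ρ at a common nerve
T2, tapering caliber, and group-wise clinical covariates — with
ground-truth lesion flags retained for testing.

## Worked example

```python
import nervequant as nq
from nervequant import classification as cls, mapping

cfg = nq.CohortConfig(seed=7, group_sizes={"control": 25, "severe": 10},
                      territories=("tibial",))
subjects, voxels = nq.generate_cohort(cfg)
frame = nq.subjects_to_frame(subjects)

control_ids = frame.loc[frame["group"] == "control", "subject_id"]
models = cls.build_control_models(voxels[voxels["subject_id"].isin(control_ids)])
calls = cls.classify(cls.normalize(voxels, models), threshold=1.5)

profile = mapping.slice_profile(calls, side_aggregation="mean")
burdens = mapping.region_burden(profile)
print(burdens.merge(frame[["subject_id", "group"]], on="subject_id")
             .groupby("group")[["proximal_mean", "distal_mean"]].mean().round(1))
```

prints

```
         proximal_mean  distal_mean
group
control           18.0          8.0
severe            57.3         22.4
```

i.e. the classifier + mapper recover the planted regional lesion rates:
severe DPN carries ~57 lesion voxels per proximal slice against ~18 in
controls, with a marked proximal-to-distal gradient (57 → 22). The
`examples/` directory holds one short script per capability (simulation,
classification + mapping, relaxometry, severity statistics); each prints
the numbers it computes and what they mean. A thin CLI covers the same
stages (`nervequant simulate | extract | classify | map | relaxometry |
stats | run-all`).

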