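"""Classify lesion voxels against the control reference and map their
proximal-to-distal distribution.

Normalizes every nerve voxel by the modal intensity of the matching control
stratum (slice x territory x side, 100-bin histogram), calls voxels above
1.5x the control mode lesions, and averages the per-slice lesion counts over
the proximal (21-46) and distal (95-120) windows.
"""

import nervequant as nq
from nervequant import classification as cls
from nervequant import mapping

cfg = nq.CohortConfig(seed=7, group_sizes={"control": 25, "severe": 10},
                      territories=("tibial",))
subjects, voxels = nq.generate_cohort(cfg)
frame = nq.subjects_to_frame(subjects)

control_ids = frame.loc[frame["group"] == "control", "subject_id"]
models = cls.build_control_models(voxels[voxels["subject_id"].isin(control_ids)])
calls = cls.classify(cls.normalize(voxels, models), threshold=1.5)

exact = (calls["is_lesion"] == calls["ground_truth_lesion"]).all()
print(f"strata modeled: {len(models)};  calls match planted truth: {exact}")

profile = mapping.slice_profile(calls, side_aggregation="mean")
burdens = mapping.region_burden(profile)
summary = (
    burdens.merge(frame[["subject_id", "group"]], on="subject_id")
    .groupby("group")[["proximal_mean", "distal_mean"]]
    .mean()
    .round(1)
)
print("\nlesion voxels per slice (group means):")
print(summary)
# The severe group shows the proximal predominance (high proximal mean,
# lower distal mean); controls sit near their planted background rates.
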