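"""Shared fixtures: small synthetic cohorts sized for fast tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import nervequant as nq
from nervequant import classification as cls


def small_cohort_config(seed: int = 0, **overrides) -> nq.CohortConfig:
    """A down-scaled cohort: full slice grids, fewer subjects and thinner
    nerves, with lesion rates scaled to stay plantable."""
    defaults = dict(
        seed=seed,
        group_sizes={"control": 8, "no_dpn": 4, "mild_moderate": 6, "severe": 4},
        # tighter spreads than the full-size defaults: the thin control
        # strata of the scaled cohort still pin the histogram mode, so the
        # noiseless classification oracle stays exact
        baseline_intensity_sd=5.0,
        lesion_intensity_sd=4.0,
        caliber_mean_voxels_per_slice={
            "tibial": {"control": 30, "no_dpn": 33, "mild_moderate": 34, "severe": 40},
            "peroneal": {"control": 14, "no_dpn": 14, "mild_moderate": 15, "severe": 17},
        },
        lesion_rate_proximal={
            "control": 4.0,
            "no_dpn": 5.0,
            "mild_moderate": 8.0,
            "severe": 13.0,
        },
        lesion_rate_distal={
            "control": 2.0,
            "no_dpn": 2.0,
            "mild_moderate": 3.0,
            "severe": 5.0,
        },
    )
    defaults.update(overrides)
    return nq.CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    subjects, voxels = nq.generate_cohort(small_cohort_config(seed=42))
    return nq.subjects_to_frame(subjects), voxels


@pytest.fixture(scope="session")
def classified_small(small_cohort):
    """Control models + classified calls for the small cohort."""
    subjects, voxels = small_cohort
    control_ids = subjects.loc[subjects["group"] == "control", "subject_id"]
    models = cls.build_control_models(voxels[voxels["subject_id"].isin(control_ids)])
    calls = cls.classify(cls.normalize(voxels, models), 1.5)
    return subjects, calls, models
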