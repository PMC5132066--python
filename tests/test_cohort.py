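"""Synthetic-cohort generator: structure, determinism, planted moments."""

import numpy as np
import pandas as pd
import pytest

import nervequant as nq
from nervequant.cohort import (
    SubjectRecord,
    generate_covariates,
    lesion_rate_profile,
    synthesize_dual_echo,
)

from conftest import small_cohort_config


class TestConfig:
    def test_default_group_sizes(self):
        cfg = nq.CohortConfig()
        assert cfg.group_sizes == {
            "control": 25,
            "no_dpn": 15,
            "mild_moderate": 25,
            "severe": 10,
        }

    @pytest.mark.parametrize(
        "overrides",
        [
            {"group_sizes": {"control": 0}},
            {"te1_ms": 80.0},  # te1 >= te2
            {"noise_sd": -1.0},
            {"lesion_rate_proximal": {"control": -3.0}},
            # more lesions than the thinnest slice can hold
            {"lesion_rate_proximal": {"control": 500.0}},
        ],
    )
    def test_invalid_config_rejected(self, overrides):
        cfg = nq.CohortConfig(**overrides)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_config_roundtrip(self, tmp_path):
        cfg = small_cohort_config(seed=7, noise_sd=1.5)
        path = tmp_path / "cohort.yaml"
        nq.save_config(cfg, path)
        assert nq.load_cohort_config(path) == cfg
        acfg = nq.AnalysisConfig(lesion_threshold=1.7)
        nq.save_config(acfg, tmp_path / "analysis.yaml")
        assert nq.load_analysis_config(tmp_path / "analysis.yaml") == acfg


class TestDualEcho:
    def test_noiseless_closed_form(self):
        si1, si2 = synthesize_dual_echo(360.0, 60.0, 12.0, 73.0)
        assert si1 == pytest.approx(360 * np.exp(-12 / 60))
        assert si2 == pytest.approx(360 * np.exp(-73 / 60))
        assert si1 == pytest.approx(294.74, abs=0.01)
        assert si2 == pytest.approx(106.64, abs=0.01)

    def test_infinite_t2_limit(self):
        si1, si2 = synthesize_dual_echo(1.0, 1e9)
        assert si1 == pytest.approx(1.0, abs=1e-6)
        assert si2 == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("bad", [{"rho": 0.0}, {"t2_ms": -5.0}])
    def test_invalid_inputs(self, bad):
        kwargs = dict(rho=100.0, t2_ms=60.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            synthesize_dual_echo(**kwargs)

    def test_rician_noise_is_nonnegative(self):
        rng = np.random.default_rng(0)
        si1, si2 = synthesize_dual_echo(
            np.full(2000, 5.0), 60.0, noise_sd=4.0, rng=rng, noise_model="rician"
        )
        assert (si1 >= 0).all() and (si2 >= 0).all()


class TestLesionRateProfile:
    def test_anchor_means_exact(self):
        s = np.arange(1, 141)
        rate = lesion_rate_profile(s, 57.0, 22.0)
        assert rate[20:46].mean() == pytest.approx(57.0)
        assert rate[94:120].mean() == pytest.approx(22.0)

    def test_monotone_between_anchors(self):
        rate = lesion_rate_profile(np.arange(1, 141), 57.0, 22.0)
        mid = rate[46:94]
        assert (np.diff(mid) <= 0).all()
        assert rate[0] == 57.0 and rate[-1] == 22.0


class TestGenerateCohort:
    def test_one_record_per_subject_and_full_grid(self, small_cohort):
        subjects, voxels = small_cohort
        assert len(subjects) == 22
        # every (subject, side, territory) covers its full slice axis
        cover = voxels.groupby(["subject_id", "side", "territory"])["slice"].agg(
            ["min", "max"]
        )
        for (_, _, terr), row in cover.iterrows():
            assert row["min"] == 1
            assert row["max"] == {"tibial": 140, "peroneal": 60}[terr]

    def test_determinism_byte_identical(self):
        cfg = small_cohort_config(seed=11, group_sizes={"control": 3, "severe": 2})
        _, v1 = nq.generate_cohort(cfg)
        _, v2 = nq.generate_cohort(small_cohort_config(seed=11, group_sizes={"control": 3, "severe": 2}))
        assert v1.to_csv(index=False) == v2.to_csv(index=False)
        _, v3 = nq.generate_cohort(small_cohort_config(seed=12, group_sizes={"control": 3, "severe": 2}))
        assert v1.to_csv(index=False) != v3.to_csv(index=False)

    def test_zero_lesion_rates_plant_nothing(self):
        cfg = small_cohort_config(
            seed=5,
            lesion_rate_proximal={g: 0.0 for g in nq.GROUPS},
            lesion_rate_distal={g: 0.0 for g in nq.GROUPS},
        )
        _, voxels = nq.generate_cohort(cfg)
        assert voxels["ground_truth_lesion"].sum() == 0

    def test_lesions_never_exceed_slice_voxels(self, small_cohort):
        _, voxels = small_cohort
        per_slice = voxels.groupby(["subject_id", "side", "territory", "slice"]).agg(
            lesions=("ground_truth_lesion", "sum"), voxels=("voxel_id", "size")
        )
        assert (per_slice["lesions"] <= per_slice["voxels"]).all()

    def test_planted_proximal_mean_matches_rate(self):
        # single severe subject, tibial only, across seeds: the mean planted
        # lesion count over slices 21-46 converges to the configured rate
        means = []
        for seed in range(200):
            cfg = nq.CohortConfig(
                group_sizes={"severe": 1},
                territories=("tibial",),
                sides=("L",),
                seed=seed,
            )
            _, voxels = nq.generate_cohort(cfg)
            window = voxels[(voxels["slice"] >= 21) & (voxels["slice"] <= 46)]
            means.append(
                window.groupby("slice")["ground_truth_lesion"].sum().mean()
            )
        assert np.mean(means) == pytest.approx(57.0, abs=2.0)

    def test_proximal_exceeds_distal_in_expectation(self, small_cohort):
        subjects, voxels = small_cohort
        severe = subjects.loc[subjects["group"] == "severe", "subject_id"]
        sv = voxels[voxels["subject_id"].isin(severe) & (voxels["territory"] == "tibial")]
        prox = sv[(sv["slice"] >= 21) & (sv["slice"] <= 46)]
        dist = sv[(sv["slice"] >= 95) & (sv["slice"] <= 120)]
        assert (
            prox.groupby("slice")["ground_truth_lesion"].sum().mean()
            > dist.groupby("slice")["ground_truth_lesion"].sum().mean()
        )

    def test_caliber_moments(self, small_cohort):
        subjects, voxels = small_cohort
        cfg = small_cohort_config()
        ctrl = subjects.loc[subjects["group"] == "control", "subject_id"]
        counts = (
            voxels[voxels["subject_id"].isin(ctrl) & (voxels["territory"] == "tibial")]
            .groupby(["subject_id", "side", "slice"])
            .size()
        )
        expected = cfg.caliber_mean_voxels_per_slice["tibial"]["control"]
        se = np.sqrt(expected / len(counts))
        assert counts.mean() == pytest.approx(expected, abs=3 * se)

    def test_dual_echo_only_on_thigh_slab(self, small_cohort):
        _, voxels = small_cohort
        has = voxels["si_te1"].notna()
        in_slab = (
            (voxels["territory"] == "tibial")
            & (voxels["slice"] >= 36)
            & (voxels["slice"] <= 70)
        )
        assert (has == in_slab).all()


class TestCovariates:
    def _replicates(self, group, n, seed=0, sd_scale=1.0):
        rng = np.random.default_rng(seed)
        subs = [SubjectRecord(subject_id=f"s{i}", group=group) for i in range(n)]
        return generate_covariates(subs, nq.CohortConfig(), rng, sd_scale=sd_scale)

    def test_severe_nds_mean(self):
        subs = self._replicates("severe", 10_000, seed=3)
        assert np.mean([s.nds for s in subs]) == pytest.approx(7.4, abs=0.1)

    def test_mild_moderate_retinopathy_prevalence(self):
        subs = self._replicates("mild_moderate", 10_000, seed=4)
        assert np.mean([s.retinopathy for s in subs]) == pytest.approx(0.32, abs=0.02)

    def test_zero_variance_hits_group_means(self):
        subs = self._replicates("no_dpn", 5, seed=1, sd_scale=0.0)
        for s in subs:
            assert s.nss == pytest.approx(0.9)
            assert s.dm_duration == pytest.approx(28.7)
            assert s.hba1c == pytest.approx(7.73)

    def test_invalid_subject_rejected(self):
        with pytest.raises(ValueError):
            SubjectRecord(subject_id="x", group="mystery")
        with pytest.raises(ValueError):
            SubjectRecord(subject_id="x", group="severe", nds=-1.0)
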