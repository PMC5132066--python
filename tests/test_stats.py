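"""Statistical layer: ANOVAs, Holm, ordinal regression, ROC, stepwise."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from nervequant import stats as st


class TestOneWayAnova:
    def test_identical_groups_f_zero(self):
        r = st.one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert r.f == 0.0

    def test_hand_decomposition(self):
        r = st.one_way_anova({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert r.f == pytest.approx(13.5)
        assert (r.df_between, r.df_within) == (1, 4)
        assert 0 < r.p < 0.05

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        a, b, c = rng.normal(0, 1, 10), rng.normal(1, 1, 12), rng.normal(2, 1, 8)
        r1 = st.one_way_anova({"a": a, "b": b, "c": c})
        r2 = st.one_way_anova({"a": a + 100, "b": b + 100, "c": c + 100})
        assert r1.f == pytest.approx(r2.f)

    def test_matches_scipy(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(3)
        groups = {k: rng.normal(i, 1, 9 + i) for i, k in enumerate("abcd")}
        r = st.one_way_anova(groups)
        ref = f_oneway(*groups.values())
        assert r.f == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)

    def test_pairwise_contrasts_holm_dominates(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(i * 0.5, 1, 12) for i, k in enumerate("abcd")}
        r = st.one_way_anova(groups)
        assert len(r.contrasts) == 6
        assert (r.contrasts["p_holm"] >= r.contrasts["p"] - 1e-15).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            st.one_way_anova({"a": [1.0], "b": []})


class TestHolm:
    def test_worked_example(self):
        np.testing.assert_allclose(
            st.holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_single_p_unchanged(self):
        assert st.holm_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert (st.holm_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    @staticmethod
    def _brute_force(p):
        # step-down: sort, multiply by (m - rank), enforce monotonicity, cap
        p = np.asarray(p, float)
        m = p.size
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min((m - rank) * p[idx], 1.0))
            adj[idx] = running
        return adj

    def test_against_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.random(rng.integers(1, 12))
            np.testing.assert_allclose(st.holm_adjust(p), self._brute_force(p))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        p = rng.random(8)
        perm = rng.permutation(8)
        np.testing.assert_allclose(st.holm_adjust(p)[perm], st.holm_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.holm_adjust([0.5, 1.2])


def _split_plot_data(seed=0, shifts=(0.0, 4.0, 9.0), ns=(10, 12, 8)):
    rng = np.random.default_rng(seed)
    rows = []
    for gi, (shift, n) in enumerate(zip(shifts, ns)):
        for i in range(n):
            sid = f"g{gi}s{i}"
            rows.append(
                {
                    "subject_id": sid,
                    "group": f"g{gi}",
                    "proximal": rng.normal(20 + shift, 4),
                    "distal": rng.normal(8, 3),
                }
            )
    df = pd.DataFrame(rows)
    return df, dict(zip(df["subject_id"], df["group"]))


class TestRmAnova:
    def test_no_location_difference_gives_f_zero(self):
        df, groups = _split_plot_data()
        df["distal"] = df["proximal"]
        r = st.rm_anova_group_by_location(df, groups)
        assert r["location"].f == 0.0
        assert r["interaction"].f == 0.0

    def test_interaction_equals_difference_score_anova(self):
        df, groups = _split_plot_data(seed=2)
        r = st.rm_anova_group_by_location(df, groups)
        d = df.assign(diff=df["proximal"] - df["distal"])
        ow = st.one_way_anova(
            {g: sub["diff"].to_numpy() for g, sub in d.groupby("group")},
            pairwise=False,
        )
        assert r["interaction"].f == pytest.approx(ow.f)
        assert r["interaction"].p == pytest.approx(ow.p)
        assert (r["interaction"].df_between, r["interaction"].df_within) == (
            ow.df_between,
            ow.df_within,
        )

    def test_matches_pingouin_mixed_anova_balanced(self):
        pingouin = pytest.importorskip("pingouin")
        df, groups = _split_plot_data(seed=3, ns=(10, 10, 10))
        long = pd.concat(
            [
                df.assign(location="proximal", value=df["proximal"]),
                df.assign(location="distal", value=df["distal"]),
            ]
        )
        ref = pingouin.mixed_anova(
            long, dv="value", within="location", between="group", subject="subject_id"
        ).set_index("Source")
        r = st.rm_anova_group_by_location(df, groups)
        assert r["group"].f == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert r["interaction"].f == pytest.approx(ref.loc["Interaction", "F"], rel=1e-6)

    def test_missing_location_dropped_with_warning(self):
        df, groups = _split_plot_data()
        df.loc[0, "distal"] = np.nan
        with pytest.warns(UserWarning, match="dropped"):
            r = st.rm_anova_group_by_location(df, groups)
        assert r["group"].df_within == len(df) - 1 - 3

    def test_planted_interaction_detected_across_seeds(self):
        # group-dependent proximal-distal gap: interaction should be
        # significant in most replicates at these effect sizes
        hits = 0
        for seed in range(20):
            df, groups = _split_plot_data(seed=seed, shifts=(0.0, 6.0, 12.0))
            r = st.rm_anova_group_by_location(df, groups)
            hits += r["interaction"].p < 0.05
        assert hits >= 16


def _po_sample(rng, n, beta_per_unit, rho_range=(200.0, 500.0)):
    rho = rng.uniform(*rho_range, n)
    eta = beta_per_unit * rho
    cuts = np.quantile(eta, [0.25, 0.5, 0.75])
    u = rng.random(n)
    cdf = [expit(c - eta) for c in cuts]
    y = np.select([u < cdf[0], u < cdf[1], u < cdf[2]], [0, 1, 2], default=3)
    return rho, y


class TestOrdinalRegression:
    def test_null_effect_recovers_or_one(self):
        rng = np.random.default_rng(8)
        n = 4000
        rho = rng.uniform(200, 500, n)
        y = rng.integers(0, 4, n)  # severity independent of rho
        res = st.ordinal_regression(rho, y)
        lo, hi = res.or_ci_per_100
        assert lo < 1.0 < hi
        assert res.or_per_100 == pytest.approx(1.0, abs=0.15)

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(9)
        rho, y = _po_sample(rng, 5000, np.log(2.9) / 100.0)
        res = st.ordinal_regression(rho, y)
        assert res.or_per_100 == pytest.approx(2.9, abs=0.3)
        assert res.p < 0.001

    def test_bias_shrinks_with_n(self):
        errs = {}
        for n in (500, 5000):
            est = []
            for seed in range(6):
                rng = np.random.default_rng(100 + seed)
                rho, y = _po_sample(rng, n, np.log(2.0) / 100.0)
                est.append(np.log(st.ordinal_regression(rho, y).or_per_100))
            errs[n] = abs(np.mean(est) - np.log(2.0))
        assert errs[5000] < errs[500] + 0.05

    def test_cumulative_curves_monotone(self):
        rng = np.random.default_rng(10)
        rho, y = _po_sample(rng, 2000, np.log(2.5) / 100.0)
        res = st.ordinal_regression(rho, y)
        cc = res.cumulative_curves
        for col in cc.columns[1:]:
            assert (np.diff(cc[col]) >= -1e-12).all()
            assert cc[col].between(0, 1).all()
        # category order: P(>= mild) >= P(>= severe) pointwise
        cols = cc.columns[1:]
        for a, b in zip(cols, cols[1:]):
            assert (cc[a] >= cc[b] - 1e-12).all()

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="3 observed"):
            st.ordinal_regression([1.0, 2.0, 3.0], [0, 1, 0])


class TestRoc:
    def test_identical_distributions_auc_half(self):
        rng = np.random.default_rng(21)
        s = rng.normal(0, 1, 4000)
        y = np.r_[np.ones(2000, int), np.zeros(2000, int)]
        r = st.roc_analysis(s, y, thresholds=(0.0,), n_boot=50, seed=0)
        assert r.auc == pytest.approx(0.5, abs=0.03)
        assert r.auc_ci[0] < 0.5 < r.auc_ci[1]

    def test_perfect_separation(self):
        s = np.r_[np.full(10, 10.0), np.full(10, 1.0)]
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        r = st.roc_analysis(s, y, thresholds=(5.0,), n_boot=0)
        assert r.auc == 1.0
        ops = r.operating_points.iloc[0]
        assert ops["sensitivity_pct"] == 100.0
        assert ops["specificity_pct"] == 100.0

    def test_threshold_convention_is_ge(self):
        s = np.array([294.0, 100.0])
        y = np.array([1, 0])
        ops = st.roc_analysis(s, y, thresholds=(294.0,), n_boot=0).operating_points
        assert ops["sensitivity_pct"].iloc[0] == 100.0  # score == t is positive
        assert ops["specificity_pct"].iloc[0] == 100.0

    def test_auc_equals_pair_counting_oracle(self):
        # exhaustive Mann-Whitney pair count, ties worth 1/2, on tiny samples
        rng = np.random.default_rng(22)
        for _ in range(10):
            pos = rng.integers(0, 8, rng.integers(2, 10)).astype(float)
            neg = rng.integers(0, 8, rng.integers(2, 10)).astype(float)
            wins = sum(
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            )
            oracle = wins / (len(pos) * len(neg))
            r = st.roc_analysis(
                np.r_[pos, neg],
                np.r_[np.ones(len(pos), int), np.zeros(len(neg), int)],
                n_boot=0,
            )
            assert r.auc == pytest.approx(oracle)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            st.roc_analysis([1.0, 2.0], [1, 1], n_boot=0)


class TestStepwise:
    @staticmethod
    def _design(rng, n=500, k_noise=9):
        X = pd.DataFrame(
            rng.normal(0, 1, (n, k_noise + 1)),
            columns=["signal"] + [f"noise{i}" for i in range(k_noise)],
        )
        y = 2.0 * X["signal"] + rng.normal(0, 1, n)
        return y, X

    def test_true_predictor_retained_noise_removed(self):
        successes = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y, X = self._design(rng)
            kept = st.stepwise_backward(y, X)
            names = set(kept["covariate"])
            if "signal" in names and len(names - {"signal"}) <= 1:
                successes += 1
        assert successes >= 18

    def test_all_noise_nearly_empty(self):
        rng = np.random.default_rng(30)
        X = pd.DataFrame(rng.normal(0, 1, (400, 8)), columns=[f"n{i}" for i in range(8)])
        y = rng.normal(0, 1, 400)
        kept = st.stepwise_backward(y, X)
        assert len(kept) <= 2

    def test_threshold_one_keeps_full_model(self):
        rng = np.random.default_rng(31)
        y, X = self._design(rng, n=100, k_noise=4)
        kept = st.stepwise_backward(y, X, threshold=1.0)
        assert set(kept["covariate"]) == set(X.columns)

    def test_collinear_dropped_with_warning(self):
        rng = np.random.default_rng(32)
        y, X = self._design(rng, n=200, k_noise=2)
        X["dup"] = 2.0 * X["signal"]
        with pytest.warns(UserWarning, match="collinear"):
            kept = st.stepwise_backward(y, X)
        assert "signal" in set(kept["covariate"]) or "dup" in set(kept["covariate"])

    def test_underdetermined_rejected(self):
        rng = np.random.default_rng(33)
        y, X = self._design(rng, n=5, k_noise=9)
        with pytest.raises(ValueError):
            st.stepwise_backward(y, X)
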