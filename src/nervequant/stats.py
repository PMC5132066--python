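"""Group-level statistics for the lesion-burden and spin-density endpoints.

Covers the study's statistical layer: one-way ANOVA of lesion burden across
the four severity groups with Holm-corrected pairwise contrasts; split-plot
(repeated-measures) ANOVA with group as the between-subjects factor and
location (proximal vs distal) as a two-level within-subjects factor;
proportional-odds ordinal regression of severity on proton spin density with
the odds ratio expressed per 100 proton-spin units; ROC analysis with
bootstrap AUC confidence intervals and sensitivity/specificity at named
thresholds (``score >= t`` calls positive); and backward stepwise OLS of
spin density on clinical covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .config import GROUPS

__all__ = [
    "AnovaResult",
    "OrdinalModelResult",
    "RocResult",
    "one_way_anova",
    "rm_anova_group_by_location",
    "holm_adjust",
    "ordinal_regression",
    "roc_analysis",
    "stepwise_backward",
]


# ---------------------------------------------------------------------------
# ANOVA


@dataclass
class AnovaResult:
    """An F test with optional Holm-adjusted pairwise contrasts."""

    effect: str
    f: float
    df_between: int
    df_within: int
    p: float
    contrasts: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        d = {
            "effect": self.effect,
            "f": self.f,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p": self.p,
        }
        if len(self.contrasts):
            d["contrasts"] = self.contrasts.to_dict(orient="records")
        return d


def _decompose(samples: Sequence[np.ndarray]) -> tuple[float, int, int, float]:
    """Classical between/within decomposition -> (F, df_b, df_w, p)."""
    k = len(samples)
    n = sum(len(s) for s in samples)
    grand = np.concatenate(samples).mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = k - 1, n - k
    if df_b == 0 or df_w <= 0:
        raise ValueError("one-way ANOVA needs >= 2 groups and residual df > 0")
    msw = ssw / df_w
    if msw == 0:
        f = 0.0 if ssb == 0 else float("inf")
    else:
        f = (ssb / df_b) / msw
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return float(f), df_b, df_w, p


def one_way_anova(
    values_by_group: Mapping[str, Iterable[float]],
    effect: str = "group",
    pairwise: bool = True,
) -> AnovaResult:
    """One-way ANOVA across groups, with Holm-adjusted pairwise F contrasts.

    ``values_by_group`` maps group label -> per-subject values.  Pairwise
    contrasts are two-group one-way F tests for every group pair, with
    Holm-adjusted p values.
    """
    labels = list(values_by_group)
    samples = [np.asarray(list(values_by_group[g]), dtype=float) for g in labels]
    for g, s in zip(labels, samples):
        if s.size < 1:
            raise ValueError(f"group {g!r} has no observations")
    f, df_b, df_w, p = _decompose(samples)

    contrasts = pd.DataFrame()
    if pairwise and len(labels) > 1:
        rows = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                cf, cdb, cdw, cp = _decompose([samples[i], samples[j]])
                rows.append(
                    {
                        "group_a": labels[i],
                        "group_b": labels[j],
                        "f": cf,
                        "df_between": cdb,
                        "df_within": cdw,
                        "p": cp,
                    }
                )
        contrasts = pd.DataFrame(rows)
        contrasts["p_holm"] = holm_adjust(contrasts["p"].to_numpy())
    return AnovaResult(effect, f, df_b, df_w, p, contrasts)


def rm_anova_group_by_location(
    burdens: pd.DataFrame,
    groups: Mapping[str, str],
) -> dict[str, AnovaResult]:
    """Split-plot ANOVA: group (between) x location (within, 2 levels).

    ``burdens`` needs columns ``subject_id, proximal, distal``; subjects
    missing either location are dropped with a warning.  With a two-level
    within factor the decomposition reduces to two one-way problems: the
    between-subjects group test is the one-way ANOVA of subject means, the
    group x location interaction is the one-way ANOVA of the
    proximal-distal differences, and the location main effect tests the
    (weighted) grand mean difference against the same within-subject error.

    Returns ``{"group": ..., "location": ..., "interaction": ...}``.
    """
    df = burdens.copy()
    ok = df["proximal"].notna() & df["distal"].notna()
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} subjects missing a location were dropped",
            stacklevel=2,
        )
        df = df[ok]
    df["group"] = df["subject_id"].map(groups)
    if df["group"].isna().any():
        raise ValueError("subjects without group label")
    levels = [g for g in df["group"].unique()]
    means = {g: (df.loc[df["group"] == g, ["proximal", "distal"]].mean(axis=1)).to_numpy() for g in levels}
    diffs = {g: (df.loc[df["group"] == g, "proximal"] - df.loc[df["group"] == g, "distal"]).to_numpy() for g in levels}

    group_res = one_way_anova(means, effect="group", pairwise=False)

    inter_f, df_b, df_w, inter_p = _decompose(list(diffs.values()))
    interaction = AnovaResult("group x location", inter_f, df_b, df_w, inter_p)

    # location main effect: grand mean of the differences against the
    # within-subject error from the group model
    d_all = np.concatenate(list(diffs.values()))
    n = d_all.size
    sse = sum(((d - d.mean()) ** 2).sum() for d in diffs.values())
    mse = sse / df_w
    if mse == 0:
        loc_f = 0.0 if d_all.mean() == 0 else float("inf")
    else:
        loc_f = n * d_all.mean() ** 2 / mse
    loc_p = float(sps.f.sf(loc_f, 1, df_w)) if np.isfinite(loc_f) else 0.0
    location = AnovaResult("location", float(loc_f), 1, df_w, loc_p)
    return {"group": group_res, "location": location, "interaction": interaction}


def holm_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# ordinal regression


@dataclass
class OrdinalModelResult:
    """Proportional-odds fit of ordinal severity on a single predictor."""

    coef_per_unit: float
    se_per_unit: float
    or_per_100: float
    or_ci_per_100: tuple[float, float]
    p: float
    cutpoints: np.ndarray
    levels: tuple[str, ...]
    converged: bool
    separation_flag: bool
    #: cumulative P(severity >= level) over a predictor grid, per level
    cumulative_curves: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "coef_per_unit": self.coef_per_unit,
            "or_per_100": self.or_per_100,
            "or_ci_per_100": list(self.or_ci_per_100),
            "p": self.p,
            "cutpoints": list(np.asarray(self.cutpoints, float)),
            "levels": list(self.levels),
            "converged": self.converged,
            "separation_flag": self.separation_flag,
        }


def ordinal_regression(
    rho: Iterable[float],
    severity: Iterable,
    levels: Sequence[str] = GROUPS,
    grid: Optional[np.ndarray] = None,
) -> OrdinalModelResult:
    """Proportional-odds (ordered logistic) regression of severity on rho.

    ``severity`` holds ordered category labels (subset of ``levels``) or
    integer codes.  The model is fit by maximum likelihood on rho/100, so
    the reported odds ratio is per 100 proton-spin units: a subject with
    100 more proton spins has ``or_per_100`` times the odds of presenting
    with higher symptom severity.  Wald 95% CI.  Predicted cumulative
    probability curves P(severity >= level | rho) are evaluated on ``grid``
    (default: 200 points spanning the observed rho range).
    """
    rho = np.asarray(list(rho), dtype=float)
    sev = pd.Series(list(severity))
    if not np.all(np.isfinite(rho)):
        raise ValueError("rho must be finite")
    if sev.dtype.kind in "iu":
        codes = sev.to_numpy(int)
    else:
        codes = sev.map({g: i for i, g in enumerate(levels)}).to_numpy()
        if np.any(pd.isna(codes)):
            raise ValueError("severity labels outside the configured levels")
        codes = codes.astype(int)
    observed = np.unique(codes)
    if observed.size < 3:
        raise ValueError("ordinal regression needs >= 3 observed severity levels")

    x = rho / 100.0  # fit on the reporting scale directly
    cat = pd.Series(
        pd.Categorical(codes, categories=sorted(observed), ordered=True)
    )
    model = OrderedModel(cat, pd.DataFrame({"rho_100": x}), distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=500, disp=False)
    beta100 = float(res.params["rho_100"])
    se100 = float(res.bse["rho_100"])
    separation = (not res.mle_retvals.get("converged", True)) or se100 > 50
    ci = (
        (float(np.exp(beta100 - 1.959963984540054 * se100)),
         float(np.exp(beta100 + 1.959963984540054 * se100)))
        if not separation
        else (0.0, float("inf"))
    )
    p = float(res.pvalues["rho_100"])

    if grid is None:
        grid = np.linspace(rho.min(), rho.max(), 200)
    grid = np.asarray(grid, dtype=float)
    cut = np.asarray(res.params.iloc[1:], dtype=float)
    # OrderedModel parameterizes thresholds incrementally: first raw, rest
    # log-increments.
    thresholds = np.cumsum(np.concatenate(([cut[0]], np.exp(cut[1:]))))
    eta = beta100 * (grid / 100.0)
    curves = {"rho": grid}
    lvl_names = [levels[i] if i < len(levels) else str(i) for i in sorted(observed)]
    for j, name in enumerate(lvl_names[1:], start=1):
        # P(severity >= level j) = logistic(eta - threshold_{j-1})
        curves[f"p_ge_{name}"] = 1.0 / (1.0 + np.exp(-(eta - thresholds[j - 1])))
    return OrdinalModelResult(
        coef_per_unit=beta100 / 100.0,
        se_per_unit=se100 / 100.0,
        or_per_100=float(np.exp(beta100)),
        or_ci_per_100=ci,
        p=p,
        cutpoints=thresholds,
        levels=tuple(lvl_names),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation_flag=bool(separation),
        cumulative_curves=pd.DataFrame(curves),
    )


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    """Empirical ROC of a score for a binary outcome."""

    auc: float
    auc_ci: tuple[float, float]
    curve: pd.DataFrame
    operating_points: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "operating_points": self.operating_points.to_dict(orient="records"),
        }


def roc_analysis(
    scores: Iterable[float],
    labels: Iterable[int],
    thresholds: Sequence[float] = (294.0, 336.0, 357.0),
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """Empirical AUC with stratified-bootstrap CI and named operating points.

    ``labels`` are 1 for the positive class (symptomatic DPN) and 0 for the
    negative class (nondiabetic controls).  The empirical AUC equals the
    normalized Mann-Whitney U statistic.  At each named threshold t the rule
    ``score >= t`` calls a subject positive, so sensitivity =
    P(score >= t | positive) and specificity = P(score < t | negative);
    both are reported in percent.
    """
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    rng = np.random.default_rng(seed)
    pos, neg = s[y == 1], s[y == 0]
    if n_boot > 0:
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos, n_pos, replace=True)
            bn = rng.choice(neg, n_neg, replace=True)
            boots[b] = roc_auc_score(
                np.r_[np.ones(n_pos), np.zeros(n_neg)], np.r_[bp, bn]
            )
        ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
    else:
        ci = (float("nan"), float("nan"))

    ops = pd.DataFrame(
        {
            "threshold": list(thresholds),
            "sensitivity_pct": [100.0 * float(np.mean(pos >= t)) for t in thresholds],
            "specificity_pct": [100.0 * float(np.mean(neg < t)) for t in thresholds],
        }
    )
    return RocResult(auc, ci, curve, ops)


# ---------------------------------------------------------------------------
# backward stepwise regression


def stepwise_backward(
    y: Iterable[float],
    covariates: pd.DataFrame,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Backward stepwise OLS: drop the least significant covariate until
    all retained covariates have p <= threshold.

    Perfectly collinear covariates are dropped (with a warning) before
    stepping.  Returns the retained covariates with coefficients, 95% CIs
    and p values; an intercept is always included and not eligible for
    removal.  ``threshold=1`` returns the full model.
    """
    y = np.asarray(list(y), dtype=float)
    X = covariates.copy().astype(float)
    if len(X) != y.size:
        raise ValueError("y and covariates must have equal length")
    if len(X) <= X.shape[1]:
        raise ValueError("need more observations than covariates")

    # drop exactly collinear columns via pivoted QR on the centered design
    keep = list(X.columns)
    Z = X[keep].to_numpy()
    Zc = np.c_[np.ones(len(Z)), Z]
    rank = np.linalg.matrix_rank(Zc)
    while rank < Zc.shape[1] and keep:
        dropped = None
        for col in reversed(keep):
            trial = [c for c in keep if c != col]
            Zt = np.c_[np.ones(len(X)), X[trial].to_numpy()]
            if np.linalg.matrix_rank(Zt) == Zt.shape[1]:
                dropped = col
                break
        if dropped is None:
            dropped = keep[-1]
        warnings.warn(f"dropping collinear covariate {dropped!r}", stacklevel=2)
        keep.remove(dropped)
        Zc = np.c_[np.ones(len(X)), X[keep].to_numpy()]
        rank = np.linalg.matrix_rank(Zc)

    while keep:
        design = sm.add_constant(X[keep])
        fit = sm.OLS(y, design).fit()
        pvals = fit.pvalues.drop("const")
        worst = pvals.idxmax()
        if pvals[worst] <= threshold:
            break
        keep.remove(worst)

    if not keep:
        return pd.DataFrame(columns=["covariate", "coef", "ci_low", "ci_high", "p"])
    design = sm.add_constant(X[keep])
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int()
    out = pd.DataFrame(
        {
            "covariate": keep,
            "coef": [fit.params[c] for c in keep],
            "ci_low": [ci.loc[c, 0] for c in keep],
            "ci_high": [ci.loc[c, 1] for c in keep],
            "p": [fit.pvalues[c] for c in keep],
        }
    )
    return out
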