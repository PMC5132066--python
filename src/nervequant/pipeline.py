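"""End-to-end analysis pipeline: classify -> map -> relaxometry -> stats.

``run_pipeline`` consumes a subject table and a voxel table (real or
synthetic), builds the control reference histograms, classifies lesion
voxels, maps lesion burden along the proximal-to-distal axis, inverts the
dual-echo decay where dual-echo data exist, runs the group statistics and
writes a JSON report plus CSV tables.  Stages degrade gracefully: without
dual-echo columns the relaxometry and downstream spin-density statistics
are marked "skipped" while the lesion analysis completes.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import classification as cls
from . import mapping, relaxometry, stats
from .config import AnalysisConfig, GROUPS

logger = logging.getLogger("nervequant")

__all__ = ["run_pipeline"]


def _group_map(subjects: pd.DataFrame) -> dict[str, str]:
    return dict(zip(subjects["subject_id"], subjects["group"]))


def run_pipeline(
    config: AnalysisConfig,
    subjects: pd.DataFrame,
    voxels: pd.DataFrame,
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Run the full analysis; return (and optionally write) the report.

    ``subjects`` needs columns ``subject_id, group``; ``voxels`` is a
    validated voxel table.  When ``out_dir`` is given, writes
    ``report.json`` plus per-stage CSVs there.
    """
    config.validate()
    report: dict = {"config": {k: v for k, v in vars(config).items()}}
    groups = _group_map(subjects)

    # ---- classification against the nondiabetic control reference
    logger.info("building control histogram models")
    control_ids = subjects.loc[subjects["group"] == "control", "subject_id"]
    control_voxels = voxels[voxels["subject_id"].isin(control_ids)]
    if control_voxels.empty:
        raise RuntimeError("classify stage: no control voxels to build models from")
    models = cls.build_control_models(control_voxels, n_bins=config.n_bins)
    calls = cls.classify(cls.normalize(voxels, models), config.lesion_threshold)
    per_subject_counts = (
        calls.groupby("subject_id")["is_lesion"].sum().rename("lesion_voxels")
    )
    report["classification"] = {
        "threshold": config.lesion_threshold,
        "n_strata": len(models),
        "lesion_voxels_by_group": {
            g: float(
                per_subject_counts.reindex(
                    subjects.loc[subjects["group"] == g, "subject_id"], fill_value=0
                ).mean()
            )
            for g in GROUPS
            if (subjects["group"] == g).any()
        },
    }

    # ---- proximal-to-distal mapping (tibial axis)
    logger.info("mapping lesion burden along the slice axis")
    profile = mapping.slice_profile(calls, side_aggregation=config.side_aggregation)
    tib = profile[profile["territory"] == "tibial"]
    burdens = mapping.region_burden(
        tib, config.proximal_window, config.distal_window
    )
    gp = mapping.group_profiles(profile, groups)
    cal = mapping.caliber(voxels, side_aggregation=config.side_aggregation)

    burdens_g = burdens.merge(
        subjects[["subject_id", "group"]], on="subject_id", how="left"
    )
    report["mapping"] = {
        "proximal_window": list(config.proximal_window),
        "distal_window": list(config.distal_window),
        "regional_means_by_group": {
            g: {
                "proximal": float(sub["proximal_mean"].mean()),
                "distal": float(sub["distal_mean"].mean()),
            }
            for g, sub in burdens_g.groupby("group")
        },
    }

    # ---- lesion-burden statistics
    totals = calls.groupby("subject_id")["is_lesion"].sum()
    by_group = {
        g: totals.reindex(
            subjects.loc[subjects["group"] == g, "subject_id"], fill_value=0
        ).to_numpy(float)
        for g in GROUPS
        if (subjects["group"] == g).any()
    }
    anova = stats.one_way_anova(by_group, effect="group: total lesion burden")
    rm_in = burdens_g.rename(
        columns={"proximal_mean": "proximal", "distal_mean": "distal"}
    )[["subject_id", "proximal", "distal"]]
    rm = stats.rm_anova_group_by_location(rm_in, groups)
    report["lesion_stats"] = {
        "one_way_anova": anova.to_dict(),
        "rm_anova": {k: v.to_dict() for k, v in rm.items()},
    }

    # ---- relaxometry + spin-density statistics
    has_dual_echo = (
        "si_te1" in voxels.columns
        and "si_te2" in voxels.columns
        and voxels["si_te1"].notna().any()
    )
    if has_dual_echo:
        logger.info("inverting dual-echo decay on the thigh slab")
        relax = relaxometry.subject_relaxometry(
            voxels, slab=config.dual_echo_slab, te1_ms=config.te1_ms, te2_ms=config.te2_ms
        )
        relax_g = relax.merge(
            subjects[["subject_id", "group"]], on="subject_id", how="left"
        )
        report["relaxometry"] = {
            "slab": list(config.dual_echo_slab),
            "rho_by_group": {
                g: {"mean": float(sub["rho"].mean()), "sem": float(sub["rho"].sem())}
                for g, sub in relax_g.groupby("group")
            },
            "t2_by_group": {
                g: float(sub["t2_app_ms"].mean()) for g, sub in relax_g.groupby("group")
            },
        }
        valid = relax_g.dropna(subset=["rho"])
        try:
            om = stats.ordinal_regression(valid["rho"], valid["group"])
            report["ordinal"] = om.to_dict()
        except ValueError as e:
            report["ordinal"] = {"skipped": str(e)}
        symptomatic = valid["group"].isin(["mild_moderate", "severe"])
        ctrl = valid["group"] == "control"
        roc_in = valid[symptomatic | ctrl]
        try:
            roc = stats.roc_analysis(
                roc_in["rho"],
                roc_in["group"].isin(["mild_moderate", "severe"]).astype(int),
                n_boot=config.bootstrap_reps,
                seed=config.seed,
            )
            report["roc"] = roc.to_dict()
        except ValueError as e:
            report["roc"] = {"skipped": str(e)}

        # clinical covariates vs rho, diabetic subjects only
        covar_cols = [
            "age",
            "dm_duration",
            "nss",
            "nds",
            "hba1c",
            "bmi",
            "retinopathy",
            "nephropathy",
            "chd",
            "hyperlipidemia",
            "smoking",
            "body_weight",
        ]
        if all(c in subjects.columns for c in covar_cols):
            diab = subjects[subjects["group"] != "control"].merge(
                valid[["subject_id", "rho"]], on="subject_id", how="inner"
            )
            X = diab[covar_cols].astype(float)
            X["dm_type1"] = (diab.get("dm_type", pd.Series(index=diab.index)) == 1).astype(float)
            X["symptomatic_dpn"] = diab["group"].isin(["mild_moderate", "severe"]).astype(float)
            if len(diab) > X.shape[1]:
                retained = stats.stepwise_backward(diab["rho"], X)
                report["stepwise"] = retained.to_dict(orient="records")
            else:
                report["stepwise"] = {"skipped": "too few diabetic subjects"}
        else:
            report["stepwise"] = {"skipped": "covariates missing"}
    else:
        logger.info("no dual-echo columns; skipping relaxometry")
        report["relaxometry"] = {"skipped": "no dual-echo data"}
        report["ordinal"] = {"skipped": "no dual-echo data"}
        report["roc"] = {"skipped": "no dual-echo data"}
        report["stepwise"] = {"skipped": "no dual-echo data"}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
        calls.to_csv(out / "lesion_calls.csv", index=False)
        profile.to_csv(out / "slice_profiles.csv", index=False)
        burdens.to_csv(out / "region_burdens.csv", index=False)
        gp.to_csv(out / "group_profiles.csv", index=False)
        cal.to_csv(out / "caliber.csv", index=False)
        if has_dual_echo:
            relax.to_csv(out / "relaxometry.csv", index=False)
        logger.info("report written to %s", out)
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
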