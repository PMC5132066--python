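"""Proximal-to-distal lesion mapping and nerve-caliber quantification.

Lesion calls are aggregated into per-slice lesion-count profiles along the
proximal-to-distal slice axis (tibial slices 1-140, peroneal 1-60), regional
burdens are averaged over the proximal (slices 21-46) and distal (slices
95-120) windows, and nerve caliber is quantified as the total volume of
segmented voxels per slice.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import N_SLICES, DEFAULT_VOXEL_VOLUME_MM3

__all__ = [
    "slice_profile",
    "region_burden",
    "caliber",
    "group_profiles",
    "plot_group_profiles",
]


def _aggregate_sides(per_side: pd.DataFrame, how: str) -> pd.DataFrame:
    """Combine L/R per-slice values into one per-leg figure per slice."""
    if how not in ("mean", "sum"):
        raise ValueError(f"unknown side aggregation {how!r}")
    grouped = per_side.groupby(["subject_id", "territory", "slice"], sort=True)["value"]
    return (grouped.mean() if how == "mean" else grouped.sum()).reset_index()


def slice_profile(
    calls: pd.DataFrame,
    side_aggregation: str = "mean",
    n_slices: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Per-slice lesion-count profile for every subject and territory.

    ``calls`` is a classified voxel table (``is_lesion`` present).  Lesion
    voxels are counted per (subject, side, territory, slice), then combined
    across sides by ``side_aggregation`` ("mean": per-leg average, the
    default; "sum": both legs summed).  Slices with no lesion voxels get 0;
    every profile spans the full slice axis of its territory.

    Returns a long table ``(subject_id, territory, slice, lesion_count)``.
    """
    if "is_lesion" not in calls:
        raise ValueError("calls must contain is_lesion; run classify() first")
    n_slices = dict(N_SLICES) if n_slices is None else dict(n_slices)

    counts = (
        calls[calls["is_lesion"]]
        .groupby(["subject_id", "side", "territory", "slice"], sort=True)
        .size()
        .rename("value")
        .reset_index()
    )
    # subjects/territories present in the data, even if lesion-free
    present = calls[["subject_id", "territory"]].drop_duplicates()
    sides_per = calls.groupby(["subject_id", "territory"])["side"].nunique()

    if side_aggregation == "mean":
        # a subject contributing one leg only falls back to that leg
        single = sides_per[sides_per < 2]
        if len(single):
            warnings.warn(
                f"{len(single)} subject/territory pairs contribute a single "
                "side; side-mean falls back to the available side",
                stacklevel=2,
            )
    agg = _aggregate_sides(counts, side_aggregation)

    pieces = []
    for _, row in present.iterrows():
        terr = row["territory"]
        ns = n_slices.get(terr)
        if ns is None:
            raise ValueError(f"no slice count known for territory {terr!r}")
        full = pd.DataFrame(
            {
                "subject_id": row["subject_id"],
                "territory": terr,
                "slice": np.arange(1, ns + 1),
            }
        )
        pieces.append(full)
    grid = pd.concat(pieces, ignore_index=True)
    out = grid.merge(agg, on=["subject_id", "territory", "slice"], how="left")
    out["lesion_count"] = out.pop("value").fillna(0.0)
    return out


def region_burden(
    profile: pd.DataFrame,
    proximal_window: tuple[int, int] = (21, 46),
    distal_window: tuple[int, int] = (95, 120),
) -> pd.DataFrame:
    """Regional and total lesion burden per subject and territory.

    ``proximal_mean`` / ``distal_mean`` are arithmetic means of the per-slice
    lesion counts over the inclusive windows; ``total`` is the sum over the
    whole slice axis.  Windows must lie within the territory's slice range.
    """
    out = []
    for (subject, terr), sub in profile.groupby(["subject_id", "territory"], sort=True):
        s = sub.set_index("slice")["lesion_count"].sort_index()
        last = int(s.index.max())
        for name, (lo, hi) in (
            ("proximal", proximal_window),
            ("distal", distal_window),
        ):
            if lo < 1 or hi > last:
                raise ValueError(
                    f"{name} window [{lo},{hi}] outside slice range 1..{last} "
                    f"({terr})"
                )
        out.append(
            {
                "subject_id": subject,
                "territory": terr,
                "proximal_mean": float(
                    s.loc[proximal_window[0] : proximal_window[1]].mean()
                ),
                "distal_mean": float(
                    s.loc[distal_window[0] : distal_window[1]].mean()
                ),
                "total": float(s.sum()),
            }
        )
    return pd.DataFrame(out)


def caliber(
    table: pd.DataFrame,
    voxel_volume_mm3: float = DEFAULT_VOXEL_VOLUME_MM3,
    side_aggregation: str = "mean",
) -> pd.DataFrame:
    """Nerve caliber: total segmented voxel volume per slice (mm^3).

    Per-slice volume = voxel count x voxel volume, side-aggregated like the
    lesion profiles.  Returns a long table ``(subject_id, territory, slice,
    volume_mm3)``; per-subject summaries are a mean over slices away.
    """
    if voxel_volume_mm3 <= 0:
        raise ValueError("voxel_volume_mm3 must be > 0")
    counts = (
        table.groupby(["subject_id", "side", "territory", "slice"], sort=True)
        .size()
        .rename("value")
        .reset_index()
    )
    agg = _aggregate_sides(counts, side_aggregation)
    agg["volume_mm3"] = agg.pop("value") * voxel_volume_mm3
    return agg


def group_profiles(
    profile: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Pointwise group mean +/- SEM of per-slice lesion counts.

    ``groups`` maps subject_id -> group label.  For a single-subject group
    the SEM is reported as 0 with ``sem_defined = False``.
    """
    df = profile.copy()
    df["group"] = df["subject_id"].map(groups)
    if df["group"].isna().any():
        bad = df.loc[df["group"].isna(), "subject_id"].unique()
        raise ValueError(f"subjects without group label: {list(bad)[:5]}")
    out = (
        df.groupby(["group", "territory", "slice"], sort=True)["lesion_count"]
        .agg(mean="mean", sem=lambda v: v.sem(), n="count")
        .reset_index()
    )
    out["sem_defined"] = out["n"] > 1
    out["sem"] = out["sem"].where(out["sem_defined"], 0.0)
    return out


def plot_group_profiles(gp: pd.DataFrame, territory: str = "tibial", ax=None):
    """Simple per-group lesion-profile plot (mean with SEM band)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    sub = gp[gp["territory"] == territory]
    for group, g in sub.groupby("group"):
        g = g.sort_values("slice")
        ax.plot(g["slice"], g["mean"], label=group)
        ax.fill_between(
            g["slice"], g["mean"] - g["sem"], g["mean"] + g["sem"], alpha=0.2
        )
    ax.set_xlabel("slice position (proximal → distal)")
    ax.set_ylabel("lesion voxels per slice")
    ax.set_title(f"{territory} lesion-voxel profile")
    ax.legend()
    return ax
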