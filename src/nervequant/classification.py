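"""Control-referenced histogram normalization and lesion-voxel classification.

The reference model is built from the nondiabetic control population: for
every stratum — a (territory, slice, side) combination — the control nerve
voxel intensities are histogrammed into 100 equal-width bins and the center
of the modal bin defines the stratum's reference intensity.  Every nerve
voxel (patient or control) is then normalized by its stratum's reference, so
the control-population mode maps to 1.0 by construction, and a voxel is
called a lesion voxel when its normalized intensity strictly exceeds the
binary threshold (default 1.5, i.e. 1.5x the control mode).

The threshold itself can be chosen operator-independently by sweeping a grid
of candidate thresholds and maximizing the one-way ANOVA F statistic of
per-subject total lesion burden across severity groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ControlHistogramModel",
    "build_control_models",
    "normalize",
    "classify",
    "sweep_threshold",
]

StratumKey = tuple  # (territory, slice, side)


@dataclass(frozen=True)
class ControlHistogramModel:
    """Per-stratum histogram of control intensities with its modal bin.

    ``peak_intensity`` is the center of the bin with the maximal count (the
    lowest-index bin on ties).  A constant-intensity stratum degenerates to a
    single-support histogram whose peak is that value.
    """

    territory: str
    slice: int
    side: str
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    peak_bin_index: int
    peak_intensity: float

    @property
    def key(self) -> StratumKey:
        return (self.territory, self.slice, self.side)


def _model_from_values(
    territory: str, slice_: int, side: str, values: np.ndarray, n_bins: int
) -> ControlHistogramModel:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        # single-support histogram: all mass in one bin at the common value
        edges = np.array([lo, hi])
        counts = np.array([values.size])
        return ControlHistogramModel(territory, slice_, side, edges, counts, 0, lo)
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    peak = int(np.argmax(counts))  # argmax takes the lowest index on ties
    center = float(0.5 * (edges[peak] + edges[peak + 1]))
    return ControlHistogramModel(territory, slice_, side, edges, counts, peak, center)


def build_control_models(
    control_voxels: pd.DataFrame, n_bins: int = 100
) -> dict[StratumKey, ControlHistogramModel]:
    """Fit one reference histogram per (territory, slice, side) stratum.

    ``control_voxels`` must hold only the nondiabetic control population.
    Peaks are located on raw counts, without smoothing.
    """
    if control_voxels.empty:
        raise ValueError("control voxel table is empty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    models: dict[StratumKey, ControlHistogramModel] = {}
    for (territory, slice_, side), sub in control_voxels.groupby(
        ["territory", "slice", "side"], sort=True
    ):
        models[(territory, int(slice_), side)] = _model_from_values(
            territory, int(slice_), side, sub["si_t2w"].to_numpy(float), n_bins
        )
    return models


def normalize(
    voxels: pd.DataFrame, models: Mapping[StratumKey, ControlHistogramModel]
) -> pd.DataFrame:
    """Divide every voxel intensity by its stratum's control peak intensity.

    Returns a copy of ``voxels`` with a ``normalized_si`` column.  Raises if
    a voxel falls in a stratum without a control model or whose reference
    intensity is zero.
    """
    keys = pd.MultiIndex.from_frame(voxels[["territory", "slice", "side"]])
    peaks = pd.Series(
        {k: m.peak_intensity for k, m in models.items()}, dtype=float
    )
    missing = keys.unique().difference(peaks.index)
    if len(missing):
        raise ValueError(
            f"no control model for {len(missing)} strata, e.g. {missing[0]}"
        )
    ref = peaks.reindex(keys).to_numpy()
    if np.any(ref <= 0):
        raise ValueError("control peak intensity must be > 0 in every stratum")
    out = voxels.copy()
    out["normalized_si"] = voxels["si_t2w"].to_numpy(float) / ref
    return out


def classify(calls: pd.DataFrame, threshold: float = 1.5) -> pd.DataFrame:
    """Flag lesion voxels: ``is_lesion = normalized_si > threshold`` (strict)."""
    if "normalized_si" not in calls:
        raise ValueError("calls must contain a normalized_si column; run normalize()")
    out = calls.copy()
    out["is_lesion"] = out["normalized_si"].to_numpy(float) > threshold
    return out


def _anova_f(counts: pd.Series, groups: pd.Series) -> float:
    """One-way ANOVA F of per-subject counts across groups (0 if degenerate)."""
    arr = counts.to_numpy(float)
    grand = arr.mean()
    ssb = ssw = 0.0
    k = 0
    for _, sub in counts.groupby(groups):
        v = sub.to_numpy(float)
        ssb += v.size * (v.mean() - grand) ** 2
        ssw += ((v - v.mean()) ** 2).sum()
        k += 1
    df_w = arr.size - k
    if df_w <= 0 or ssw == 0.0:
        return 0.0 if ssb == 0.0 else float("inf")
    return float((ssb / (k - 1)) / (ssw / df_w))


def sweep_threshold(
    calls: pd.DataFrame,
    groups: Mapping[str, str],
    grid: Iterable[float],
) -> tuple[float, pd.DataFrame]:
    """Choose the lesion threshold maximizing between-group separation.

    For each candidate threshold, per-subject total lesion counts are formed
    and the one-way ANOVA F statistic across severity groups is computed;
    the threshold with the maximal F is returned (the lowest on ties),
    together with the full criterion curve as a ``(threshold, f_statistic)``
    table.  ``groups`` maps subject_id -> group label.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    group_of = calls["subject_id"].map(groups)
    if group_of.isna().any():
        bad = calls.loc[group_of.isna(), "subject_id"].unique()
        raise ValueError(f"subjects without group label: {list(bad)[:5]}")
    if group_of.nunique() < 2:
        raise ValueError("threshold sweep requires at least two groups")

    norm = calls["normalized_si"].to_numpy(float)
    subj = calls["subject_id"]
    all_subjects = subj.unique()
    subj_groups = pd.Series({s: groups[s] for s in all_subjects})

    f_values = np.empty(grid.size)
    for i, t in enumerate(grid):
        counts = (
            pd.Series(norm > t, index=calls.index)
            .groupby(subj)
            .sum()
            .reindex(all_subjects, fill_value=0)
        )
        f_values[i] = _anova_f(counts, subj_groups)
    best = float(grid[int(np.argmax(f_values))])
    curve = pd.DataFrame({"threshold": grid, "f_statistic": f_values})
    return best, curve
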