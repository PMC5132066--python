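"""Readers and writers for voxel tables, subject tables and NIfTI volumes.

The canonical on-disk voxel table is a tidy CSV with one row per segmented
nerve voxel: ``subject_id, side, territory, slice, voxel_id, si_t2w,
si_te1, si_te2, voxel_volume_mm3[, ground_truth_lesion]``.  Slices are
1-based and ordered proximal to distal (tibial 1-140, peroneal 1-60).
Validation is strict and row-numbered: a malformed row is reported with its
position in the file.

NIfTI support ingests an image volume plus an integer label mask (labels
mapping e.g. ``{1: "tibial", 2: "peroneal"}``) into the same tidy table,
and can export a single subject/side back to a pair of volumes for
round-trip testing.  Because NIfTI axis direction is scanner-dependent, the
caller must declare whether the axial axis runs proximal to distal.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .config import N_SLICES
from .cohort import VOXEL_COLUMNS

__all__ = [
    "read_voxel_table",
    "write_voxel_table",
    "read_subject_table",
    "write_subject_table",
    "validate_voxel_table",
    "extract_from_images",
    "export_to_images",
]

REQUIRED_COLUMNS = ["subject_id", "side", "territory", "slice", "voxel_id", "si_t2w"]


class VoxelTableError(ValueError):
    """Raised when a voxel table violates the schema, with row diagnostics."""


def validate_voxel_table(df: pd.DataFrame, max_errors: int = 10) -> None:
    """Check the table invariants; raise :class:`VoxelTableError` listing
    the first offending rows (0-based positions within the table)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise VoxelTableError(f"missing required columns: {missing}")

    problems: list[str] = []

    def flag(mask: pd.Series | np.ndarray, message: str) -> None:
        idx = np.flatnonzero(np.asarray(mask))
        for i in idx[:max_errors]:
            problems.append(f"row {i}: {message}")

    flag(~df["side"].isin(["L", "R"]), "side must be L or R")
    flag(~df["territory"].isin(N_SLICES), "unknown territory")
    for terr, n in N_SLICES.items():
        m = (df["territory"] == terr) & (
            (df["slice"] < 1) | (df["slice"] > n) | (df["slice"] % 1 != 0)
        )
        flag(m, f"{terr} slice must be an integer in [1,{n}]")
    flag(df["si_t2w"] <= 0, "si_t2w must be > 0")
    for col in ("si_te1", "si_te2"):
        if col in df.columns:
            flag(df[col].notna() & (df[col] <= 0), f"{col} must be > 0 where present")
    dup = df.duplicated(
        subset=["subject_id", "side", "territory", "slice", "voxel_id"], keep=False
    )
    flag(dup, "duplicate (subject, side, territory, slice, voxel_id) key")

    if problems:
        shown = "\n".join(problems[:max_errors])
        raise VoxelTableError(f"invalid voxel table:\n{shown}")


def read_voxel_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a voxel-table CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    validate_voxel_table(df)
    df["slice"] = df["slice"].astype(int)
    df["voxel_id"] = df["voxel_id"].astype(int)
    if "ground_truth_lesion" in df.columns:
        df["ground_truth_lesion"] = df["ground_truth_lesion"].astype(bool)
    return df


def write_voxel_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a voxel table as CSV (validates first)."""
    validate_voxel_table(df)
    cols = [c for c in VOXEL_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in VOXEL_COLUMNS
    ]
    df[cols].to_csv(path, index=False)


def read_subject_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_subject_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# NIfTI


def extract_from_images(
    image: "nib.spatialimages.SpatialImage | str | Path",
    mask: "nib.spatialimages.SpatialImage | str | Path",
    labels: Optional[Mapping[int, str]] = None,
    subject_id: str = "subject",
    side: str = "L",
    proximal_to_distal: bool = True,
    voxel_volume_mm3: Optional[float] = None,
) -> pd.DataFrame:
    """Extract a tidy voxel table from an image volume and a label mask.

    ``labels`` maps mask values to territories (default ``{1: "tibial",
    2: "peroneal"}``).  The third (axial) axis indexes slices; if
    ``proximal_to_distal`` is False the slice axis is flipped so slice 1 is
    always the most proximal.  Voxel volume defaults to the product of the
    mask's voxel dimensions.
    """
    if labels is None:
        labels = {1: "tibial", 2: "peroneal"}
    img = nib.load(str(image)) if isinstance(image, (str, Path)) else image
    msk = nib.load(str(mask)) if isinstance(mask, (str, Path)) else mask
    data = np.asarray(img.dataobj, dtype=float)
    lab = np.asarray(msk.dataobj)
    if data.shape != lab.shape:
        raise ValueError(f"image shape {data.shape} != mask shape {lab.shape}")
    if voxel_volume_mm3 is None:
        zooms = msk.header.get_zooms()[:3]
        voxel_volume_mm3 = float(np.prod(zooms)) if len(zooms) == 3 else np.nan

    present = set(np.unique(lab[lab != 0]).astype(int))
    unknown = present - set(labels)
    if unknown:
        raise ValueError(f"mask contains unknown labels {sorted(unknown)}")

    n_ax = data.shape[2]
    rows = []
    for value, territory in labels.items():
        ii, jj, kk = np.nonzero(lab == value)
        if ii.size == 0:
            continue
        slice_idx = kk + 1 if proximal_to_distal else n_ax - kk
        order = np.lexsort((jj, ii, slice_idx))
        ii, jj, kk, slice_idx = ii[order], jj[order], kk[order], slice_idx[order]
        voxel_id = np.ones(ii.size, dtype=int)
        for s in np.unique(slice_idx):
            m = slice_idx == s
            voxel_id[m] = np.arange(1, int(m.sum()) + 1)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "side": side,
                    "territory": territory,
                    "slice": slice_idx.astype(int),
                    "voxel_id": voxel_id,
                    "si_t2w": data[ii, jj, kk],
                    "voxel_volume_mm3": voxel_volume_mm3,
                }
            )
        )
    if not rows:
        warnings.warn("mask is empty; returning an empty voxel table", stacklevel=2)
        return pd.DataFrame(
            columns=REQUIRED_COLUMNS + ["voxel_volume_mm3"]
        )
    out = pd.concat(rows, ignore_index=True)
    validate_voxel_table(out)
    return out


def export_to_images(
    table: pd.DataFrame,
    subject_id: str,
    side: str,
    labels: Optional[Mapping[int, str]] = None,
    voxel_dims_mm: tuple[float, float, float] = (0.4, 0.3, 3.5),
) -> tuple[nib.Nifti1Image, nib.Nifti1Image]:
    """Lay one subject/side of a voxel table out on a synthetic image grid.

    Voxels of each slice occupy consecutive in-plane rows (column index by
    territory), the axial axis is the slice axis ordered proximal to
    distal.  The geometry is synthetic — it preserves the table's keyed
    structure and intensities, not real nerve anatomy — which is all the
    extract/export round trip requires.  Returns (image, label mask).
    """
    if labels is None:
        labels = {1: "tibial", 2: "peroneal"}
    inv = {t: v for v, t in labels.items()}
    sub = table[(table["subject_id"] == subject_id) & (table["side"] == side)]
    if sub.empty:
        raise ValueError(f"no voxels for subject {subject_id!r} side {side!r}")
    n_ax = int(sub["slice"].max())
    nx = int(sub.groupby(["territory", "slice"]).size().max())
    ny = len(labels)
    data = np.zeros((nx, ny, n_ax))
    lab = np.zeros((nx, ny, n_ax), dtype=np.int16)
    for territory, g in sub.groupby("territory"):
        col = list(labels.values()).index(territory)
        for s, gs in g.groupby("slice"):
            k = int(s) - 1
            vals = gs.sort_values("voxel_id")["si_t2w"].to_numpy()
            data[: len(vals), col, k] = vals
            lab[: len(vals), col, k] = inv[territory]
    affine = np.diag([*voxel_dims_mm, 1.0])
    img = nib.Nifti1Image(data, affine)
    msk = nib.Nifti1Image(lab, affine)
    msk.header.set_zooms(voxel_dims_mm)
    img.header.set_zooms(voxel_dims_mm)
    return img, msk
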