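"""Synthetic MR-neurography cohort generator.

Emulates the data structure of a cross-sectional diabetic-polyneuropathy
(DPN) imaging study: four severity groups (nondiabetic controls, diabetes
without DPN, mild/moderate DPN, severe DPN), two legs per subject, two nerve
territories per leg (tibial, slices 1-140 proximal to distal; peroneal,
slices 1-60), a T2-weighted signal intensity per segmented nerve voxel and —
within one mid-to-distal thigh slab — dual-echo intensities obeying a
mono-exponential decay with subject-level proton spin density.

Lesion voxels are planted per slice from a Poisson draw around a
slice-position-dependent rate (piecewise-linear between a proximal anchor
region, slices 21-46, and a distal anchor region, slices 95-120) and receive
a T2-weighted intensity of ``lesion_intensity_factor`` times the background
mode, plus an elevated spin density at unchanged T2.  Ground-truth lesion
flags are kept so that every downstream stage can be tested against the
planted truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
import pandas as pd

from .config import GROUPS, GROUP_ORDER, CohortConfig

__all__ = [
    "SubjectRecord",
    "generate_cohort",
    "generate_covariates",
    "synthesize_dual_echo",
    "lesion_rate_profile",
    "subjects_to_frame",
    "COVARIATE_PARAMS",
]

#: Columns of the per-voxel table, in canonical order.
VOXEL_COLUMNS = [
    "subject_id",
    "side",
    "territory",
    "slice",
    "voxel_id",
    "si_t2w",
    "si_te1",
    "si_te2",
    "voxel_volume_mm3",
    "ground_truth_lesion",
]


@dataclass
class SubjectRecord:
    """One study participant with ordinal severity group and covariates.

    ``group`` is ordered control < no_dpn < mild_moderate < severe.  NSS and
    NDS are the Neuropathy Symptom Score and Neuropathy Disability Score;
    both are non-negative.  Continuous covariates carry their clinical units
    (age and diabetes duration in years, HbA1c in %, BMI in kg/m^2, body
    weight in kg).
    """

    subject_id: str
    group: str
    age: float = float("nan")
    dm_duration: float = 0.0
    dm_type: Optional[int] = None
    nss: float = 0.0
    nds: float = 0.0
    hba1c: float = float("nan")
    bmi: float = float("nan")
    retinopathy: bool = False
    nephropathy: bool = False
    chd: bool = False
    hyperlipidemia: bool = False
    smoking: bool = False
    body_weight: float = float("nan")

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.nss < 0 or self.nds < 0:
            raise ValueError("nss and nds must be >= 0")

    @property
    def group_code(self) -> int:
        return GROUP_ORDER[self.group]


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subject records (one row per subject)."""
    cols = [f.name for f in fields(SubjectRecord)]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in subjects])


# ---------------------------------------------------------------------------
# covariate distributions
#
# Group-wise means with standard errors (converted to SDs via SEM*sqrt(n))
# and binary-flag prevalences for the three diabetic groups; nondiabetic
# controls get matched age/sex and population-typical metabolic values.

COVARIATE_PARAMS: dict[str, dict] = {
    "no_dpn": {
        "n": 15,
        "age": (59.1, 2.3),
        "dm_duration": (28.7, 3.6),
        "nss": (0.9, 0.2),
        "nds": (0.1, 0.1),
        "hba1c": (7.73, 0.29),
        "bmi": (27.4, 1.0),
        "p_type1": 10 / 15,
        "retinopathy": 0.267,
        "nephropathy": 0.07,
        "chd": 0.07,
        "hyperlipidemia": 0.53,
        "smoking": 0.27,
    },
    "mild_moderate": {
        "n": 25,
        "age": (64.0, 1.5),
        "dm_duration": (23.0, 2.8),
        "nss": (3.8, 0.3),
        "nds": (2.6, 0.5),
        "hba1c": (7.45, 0.28),
        "bmi": (28.7, 0.9),
        "p_type1": 10 / 25,
        "retinopathy": 0.32,
        "nephropathy": 0.32,
        "chd": 0.20,
        "hyperlipidemia": 0.84,
        "smoking": 0.08,
    },
    "severe": {
        "n": 10,
        "age": (66.9, 2.6),
        "dm_duration": (17.9, 3.6),
        "nss": (6.2, 0.6),
        "nds": (7.4, 0.5),
        "hba1c": (7.79, 0.55),
        "bmi": (30.2, 1.2),
        "p_type1": 8 / 10,
        "retinopathy": 0.40,
        "nephropathy": 0.30,
        "chd": 0.20,
        "hyperlipidemia": 0.80,
        "smoking": 0.20,
    },
    # Age/sex-matched nondiabetic controls; HbA1c/BMI are population-typical
    # conventions, not study-reported values.
    "control": {
        "n": 25,
        "age": (56.4, 1.5),
        "dm_duration": (0.0, 0.0),
        "nss": (0.0, 0.0),
        "nds": (0.0, 0.0),
        "hba1c": (5.4, 0.06),
        "bmi": (26.0, 0.8),
        "p_type1": 0.0,
        "retinopathy": 0.0,
        "nephropathy": 0.0,
        "chd": 0.0,
        "hyperlipidemia": 0.0,
        "smoking": 0.0,
    },
}


def _sd(group: str, key: str) -> float:
    mean, sem = COVARIATE_PARAMS[group][key]
    return sem * math.sqrt(COVARIATE_PARAMS[group]["n"])


def generate_covariates(
    subjects: list[SubjectRecord],
    config: CohortConfig,
    rng: np.random.Generator,
    sd_scale: float = 1.0,
) -> list[SubjectRecord]:
    """Fill clinical covariates from group-wise distributions.

    Continuous covariates are normal draws with the group mean and
    SD = SEM * sqrt(n), clipped below at 0 where the score demands it;
    binary flags are Bernoulli draws with the group prevalence.
    ``sd_scale=0`` gives every subject its group mean exactly.
    """
    for s in subjects:
        p = COVARIATE_PARAMS[s.group]
        draw = lambda key: rng.normal(p[key][0], _sd(s.group, key) * sd_scale)
        s.age = max(draw("age"), 18.0)
        s.nss = max(draw("nss"), 0.0)
        s.nds = max(draw("nds"), 0.0)
        s.hba1c = max(draw("hba1c"), 3.0)
        s.bmi = max(draw("bmi"), 12.0)
        if s.group == "control":
            s.dm_duration, s.dm_type = 0.0, None
        else:
            s.dm_duration = max(draw("dm_duration"), 0.0)
            s.dm_type = 1 if rng.random() < p["p_type1"] else 2
        for flag in ("retinopathy", "nephropathy", "chd", "hyperlipidemia", "smoking"):
            setattr(s, flag, bool(rng.random() < p[flag]))
        # weight from BMI and a drawn body height (m)
        height = rng.normal(1.70, 0.09 * sd_scale) if sd_scale else 1.70
        s.body_weight = s.bmi * height**2
    return subjects


# ---------------------------------------------------------------------------
# signal synthesis


def synthesize_dual_echo(
    rho,
    t2_ms,
    te1_ms: float = 12.0,
    te2_ms: float = 73.0,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    noise_model: str = "gaussian",
):
    """Dual-echo signals from a mono-exponential decay.

    Noiseless signals are ``si_te = rho * exp(-te / t2)``.  Gaussian noise
    adds a zero-mean perturbation per echo; Rician noise replaces each signal
    by the magnitude of (signal + n1, n2) with independent zero-mean Gaussian
    components, the magnitude-image noise model of MR.

    Parameters are scalars or arrays (broadcast); returns ``(si_te1, si_te2)``.
    """
    rho = np.asarray(rho, dtype=float)
    t2_ms = np.asarray(t2_ms, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be > 0")
    if np.any(t2_ms <= 0):
        raise ValueError("t2_ms must be > 0")
    if not (te2_ms > te1_ms > 0):
        raise ValueError("echo times must satisfy te2 > te1 > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    si1 = rho * np.exp(-te1_ms / t2_ms)
    si2 = rho * np.exp(-te2_ms / t2_ms)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng is required when noise_sd > 0")
        si1 = _add_noise(si1, noise_sd, rng, noise_model)
        si2 = _add_noise(si2, noise_sd, rng, noise_model)
    return si1, si2


def _add_noise(signal, noise_sd, rng, noise_model):
    signal = np.asarray(signal, dtype=float)
    if noise_model == "gaussian":
        return signal + rng.normal(0.0, noise_sd, size=signal.shape)
    if noise_model == "rician":
        n1 = rng.normal(0.0, noise_sd, size=signal.shape)
        n2 = rng.normal(0.0, noise_sd, size=signal.shape)
        return np.hypot(signal + n1, n2)
    raise ValueError(f"unknown noise model {noise_model!r}")


def lesion_rate_profile(
    slices: np.ndarray, prox_rate: float, dist_rate: float
) -> np.ndarray:
    """Expected lesion voxels per slice along the proximal-to-distal axis.

    Constant at the proximal anchor rate through slice 46, linear between
    the anchor regions, constant at the distal anchor rate from slice 95 on.
    The mean over slices 21-46 is exactly ``prox_rate`` and over 95-120
    exactly ``dist_rate``.
    """
    s = np.asarray(slices, dtype=float)
    rate = np.empty_like(s)
    prox_edge, dist_edge = 46.0, 95.0
    rate[s <= prox_edge] = prox_rate
    rate[s >= dist_edge] = dist_rate
    mid = (s > prox_edge) & (s < dist_edge)
    frac = (s[mid] - prox_edge) / (dist_edge - prox_edge)
    rate[mid] = prox_rate + frac * (dist_rate - prox_rate)
    return rate


def _truncated_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator, bound_sd: float = 3.0
) -> np.ndarray:
    """Normal draws truncated at mean +/- bound_sd * sd (by resampling)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size=size)
    lo, hi = mean - bound_sd * sd, mean + bound_sd * sd
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    config: Optional[CohortConfig] = None,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns the subject records (covariates filled) and the per-voxel table
    with columns ``subject_id, side, territory, slice, voxel_id, si_t2w,
    si_te1, si_te2, voxel_volume_mm3, ground_truth_lesion``.  Dual-echo
    columns are populated only for tibial slices inside the configured thigh
    slab and are NaN elsewhere.  Identical config + seed gives identical
    output.
    """
    if config is None:
        config = CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    subjects: list[SubjectRecord] = []
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        for i in range(n):
            subjects.append(
                SubjectRecord(subject_id=f"{group}_{i + 1:03d}", group=group)
            )
    generate_covariates(subjects, config, rng)

    pieces: list[pd.DataFrame] = []
    for subj in subjects:
        rho_subject = float(
            max(rng.normal(config.rho_mean[subj.group], config.rho_sd[subj.group]), 1.0)
        )
        for side in config.sides:
            for territory in config.territories:
                pieces.append(
                    _generate_leg(
                        subj, side, territory, rho_subject, config, rng
                    )
                )
    voxels = pd.concat(pieces, ignore_index=True)
    voxels = voxels[VOXEL_COLUMNS]
    return subjects, voxels


def _generate_leg(
    subj: SubjectRecord,
    side: str,
    territory: str,
    rho_subject: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_slices = config.n_slices(territory)
    slices = np.arange(1, n_slices + 1)

    # caliber: mean-preserving linear taper from proximal to distal
    caliber_mean = config.caliber_mean_voxels_per_slice[territory][subj.group]
    if n_slices > 1:
        taper = 1.0 + config.caliber_taper * (n_slices + 1 - 2 * slices) / (
            n_slices - 1
        )
    else:
        taper = np.ones(1)
    n_vox = rng.poisson(caliber_mean * taper)
    n_vox = np.maximum(n_vox, 1)  # a segmented slice has at least one voxel

    prox_rate, dist_rate = config.lesion_rate_anchors(subj.group, territory)
    rate = lesion_rate_profile(slices, prox_rate, dist_rate)
    n_lesion = np.minimum(rng.poisson(rate), n_vox)

    total = int(n_vox.sum())
    slice_col = np.repeat(slices, n_vox)
    # intra-slice voxel index; lesion voxels occupy the lowest indices
    offsets = np.concatenate(([0], np.cumsum(n_vox)))
    voxel_id = np.arange(total) - np.repeat(offsets[:-1], n_vox) + 1
    lesion = voxel_id <= np.repeat(n_lesion, n_vox)

    si = _truncated_normal(
        config.baseline_intensity_mean,
        config.baseline_intensity_sd,
        total,
        rng,
    )
    si[lesion] = _truncated_normal(
        config.lesion_intensity_factor * config.baseline_intensity_mean,
        config.lesion_intensity_sd,
        int(lesion.sum()),
        rng,
    )
    if config.noise_sd > 0:
        si = _add_noise(si, config.noise_sd, rng, config.noise_model)
    si = np.maximum(si, 1e-6)

    si1 = np.full(total, np.nan)
    si2 = np.full(total, np.nan)
    if territory == "tibial":
        slab_lo, slab_hi = config.dual_echo_slab
        in_slab = (slice_col >= slab_lo) & (slice_col <= slab_hi)
        if in_slab.any():
            rho_vox = np.where(
                lesion[in_slab], rho_subject * config.lesion_rho_factor, rho_subject
            )
            a, b = synthesize_dual_echo(
                rho_vox,
                config.t2_ms,
                config.te1_ms,
                config.te2_ms,
                noise_sd=config.noise_sd,
                rng=rng if config.noise_sd > 0 else None,
                noise_model=config.noise_model,
            )
            si1[in_slab] = np.maximum(a, 1e-6)
            si2[in_slab] = np.maximum(b, 1e-6)

    return pd.DataFrame(
        {
            "subject_id": subj.subject_id,
            "side": side,
            "territory": territory,
            "slice": slice_col.astype(int),
            "voxel_id": voxel_id.astype(int),
            "si_t2w": si,
            "si_te1": si1,
            "si_te2": si2,
            "voxel_volume_mm3": config.voxel_volume_mm3,
            "ground_truth_lesion": lesion,
        }
    )
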