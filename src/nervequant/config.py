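"""Study configuration objects.

Two dataclasses hold every tunable of the package: :class:`CohortConfig`
parameterises the synthetic-cohort generator (group sizes, lesion rates,
proton-spin-density distributions, nerve caliber, echo times) and
:class:`AnalysisConfig` parameterises the analysis pipeline (histogram bins,
lesion threshold, proximal/distal windows, side aggregation).

Both round-trip losslessly through a flat ``key: value`` text file (a flat
YAML mapping; nested mappings are flattened with dotted keys), so a cohort or
an analysis can be reproduced exactly from its config file and a seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: Ordinal severity groups, least to most affected.
GROUPS = ("control", "no_dpn", "mild_moderate", "severe")
GROUP_ORDER = {g: i for i, g in enumerate(GROUPS)}

TERRITORIES = ("tibial", "peroneal")
SIDES = ("L", "R")

#: Number of axial slices per territory, proximal (1) to distal.
N_SLICES = {"tibial": 140, "peroneal": 60}

#: In-plane 0.4 x 0.3 mm, slice thickness 3.5 mm.
DEFAULT_VOXEL_VOLUME_MM3 = 0.4 * 0.3 * 3.5


def _round_sd(sem: float, n: int) -> float:
    """Recover a group SD from a reported standard error of the mean."""
    return round(sem * math.sqrt(n), 2)


@dataclass
class CohortConfig:
    """Parameters of the synthetic MR-neurography cohort generator.

    Defaults encode the study conditions: four severity groups
    (nondiabetic control, diabetes without DPN, mild/moderate DPN, severe
    DPN) with sizes 25/15/25/10; per-leg slice grids of 140 tibial and 60
    peroneal slices; group-dependent regional lesion-voxel rates (lesion
    voxels per slice, anchored over proximal slices 21-46 and distal slices
    95-120); group-dependent proton spin density with a common nerve T2;
    and group/territory-dependent nerve caliber with proximal-to-distal
    tapering.  Dispersions reported as standard errors are converted to SDs
    as SEM * sqrt(n).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "control": 25,
            "no_dpn": 15,
            "mild_moderate": 25,
            "severe": 10,
        }
    )
    tibial_slices: int = 140
    peroneal_slices: int = 60
    sides: tuple[str, ...] = SIDES
    territories: tuple[str, ...] = TERRITORIES

    # T2-weighted signal model (arbitrary signal units).  Background voxel
    # intensities are drawn from a normal truncated at +/-3 SD, so the
    # brightest non-lesion voxel sits at 1.3x the mode while planted lesion
    # voxels sit at lesion_intensity_factor x the mode.
    baseline_intensity_mean: float = 100.0
    baseline_intensity_sd: float = 10.0
    lesion_intensity_factor: float = 1.8
    #: spread of lesion-voxel intensities around factor x mode; narrower than
    #: the background so control-stratum histograms keep their mode at the
    #: background peak even though controls carry lesion voxels too
    lesion_intensity_sd: float = 5.0

    # Expected lesion voxels per slice per leg, by group, at the proximal
    # (slices 21-46) and distal (slices 95-120) anchor regions.
    lesion_rate_proximal: dict[str, float] = field(
        default_factory=lambda: {
            "control": 18.0,
            "no_dpn": 21.0,
            "mild_moderate": 35.0,
            "severe": 57.0,
        }
    )
    lesion_rate_distal: dict[str, float] = field(
        default_factory=lambda: {
            "control": 8.0,
            "no_dpn": 8.0,
            "mild_moderate": 12.0,
            "severe": 22.0,
        }
    )
    #: "per_leg": rates are per-slice counts on each leg (so the mean of the
    #: two legs recovers the rate). "side_sum": rates are per-slice counts
    #: summed over both legs (each leg plants half the rate).
    lesion_rate_scope: str = "per_leg"

    # Proton spin density (arbitrary proton-spin units) and nerve T2.
    rho_mean: dict[str, float] = field(
        default_factory=lambda: {
            "control": 288.0,
            "no_dpn": 323.0,
            "mild_moderate": 365.0,
            "severe": 360.0,
        }
    )
    rho_sd: dict[str, float] = field(
        default_factory=lambda: {
            "control": _round_sd(13.4, 25),
            "no_dpn": _round_sd(14.4, 15),
            "mild_moderate": _round_sd(15.2, 25),
            "severe": _round_sd(22.9, 10),
        }
    )
    #: Lesion voxels carry elevated spin density at unchanged T2.
    lesion_rho_factor: float = 1.25
    t2_ms: float = 60.0
    te1_ms: float = 12.0
    te2_ms: float = 73.0
    #: Dual-echo acquisition covers one mid-to-distal thigh slab only.
    dual_echo_slab: tuple[int, int] = (36, 70)

    noise_sd: float = 0.0
    noise_model: str = "gaussian"  # or "rician"

    # Mean segmented voxels per slice, by territory and group (caliber).
    caliber_mean_voxels_per_slice: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "tibial": {
                "control": 125.7,
                "no_dpn": 143.8,
                "mild_moderate": 148.8,
                "severe": 177.1,
            },
            "peroneal": {
                "control": 56.0,
                "no_dpn": 56.2,
                "mild_moderate": 58.6,
                "severe": 69.5,
            },
        }
    )
    #: Fractional linear caliber decline from slice 1 to the last slice
    #: (mean-preserving), emulating anatomical proximal-to-distal tapering.
    caliber_taper: float = 0.3

    voxel_volume_mm3: float = DEFAULT_VOXEL_VOLUME_MM3
    seed: int = 0

    def __post_init__(self) -> None:
        self.sides = tuple(self.sides)
        self.territories = tuple(self.territories)
        self.dual_echo_slab = tuple(self.dual_echo_slab)

    def n_slices(self, territory: str) -> int:
        if territory == "tibial":
            return self.tibial_slices
        if territory == "peroneal":
            return self.peroneal_slices
        raise ValueError(f"unknown territory {territory!r}")

    def lesion_rate_anchors(self, group: str, territory: str) -> tuple[float, float]:
        """(proximal, distal) expected lesion voxels per slice per leg.

        The configured rates are defined on the tibial territory (where the
        proximal/distal mapping lives); peroneal rates are scaled by the
        group's peroneal/tibial caliber ratio so the lesion fraction per
        nerve voxel is territory-invariant.
        """
        prox = self.lesion_rate_proximal[group]
        dist = self.lesion_rate_distal[group]
        if territory == "peroneal":
            ratio = (
                self.caliber_mean_voxels_per_slice["peroneal"][group]
                / self.caliber_mean_voxels_per_slice["tibial"][group]
            )
            prox, dist = prox * ratio, dist * ratio
        if self.lesion_rate_scope == "side_sum":
            prox, dist = prox / 2.0, dist / 2.0
        return prox, dist

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n <= 0:
                raise ValueError(f"group size for {g!r} must be > 0, got {n}")
        if not (self.te2_ms > self.te1_ms > 0):
            raise ValueError("echo times must satisfy te2 > te1 > 0")
        if self.t2_ms <= 0:
            raise ValueError("t2_ms must be > 0")
        if self.tibial_slices <= 0 or self.peroneal_slices <= 0:
            raise ValueError("slice counts must be > 0")
        for name in ("lesion_rate_proximal", "lesion_rate_distal"):
            rates = getattr(self, name)
            for g, r in rates.items():
                if r < 0:
                    raise ValueError(f"{name}[{g!r}] must be >= 0, got {r}")
        for g, sd in self.rho_sd.items():
            if sd < 0:
                raise ValueError(f"rho_sd[{g!r}] must be >= 0")
        for g, m in self.rho_mean.items():
            if m <= 0:
                raise ValueError(f"rho_mean[{g!r}] must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.lesion_rate_scope not in ("per_leg", "side_sum"):
            raise ValueError(f"unknown lesion_rate_scope {self.lesion_rate_scope!r}")
        if not (0 <= self.caliber_taper < 1):
            raise ValueError("caliber_taper must be in [0, 1)")
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("voxel_volume_mm3 must be > 0")
        # More lesion voxels than nerve voxels cannot be planted on a slice.
        for terr in self.territories:
            for g in self.group_sizes:
                caliber = self.caliber_mean_voxels_per_slice[terr][g]
                min_caliber = caliber * (1 - self.caliber_taper)
                for name, rate in zip(
                    ("lesion_rate_proximal", "lesion_rate_distal"),
                    self.lesion_rate_anchors(g, terr),
                ):
                    if rate > min_caliber:
                        raise ValueError(
                            f"{name}[{g!r}] = {rate:.1f} exceeds the minimum "
                            f"{terr} caliber {min_caliber:.1f} voxels per slice"
                        )


@dataclass
class AnalysisConfig:
    """Parameters of the lesion-classification and mapping analysis."""

    n_bins: int = 100
    lesion_threshold: float = 1.5
    proximal_window: tuple[int, int] = (21, 46)
    distal_window: tuple[int, int] = (95, 120)
    te1_ms: float = 12.0
    te2_ms: float = 73.0
    dual_echo_slab: tuple[int, int] = (36, 70)
    side_aggregation: str = "mean"  # or "sum"
    alpha: float = 0.05
    bootstrap_reps: int = 2000
    sweep_grid: tuple[float, float, float] = (1.05, 3.00, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        self.proximal_window = tuple(self.proximal_window)
        self.distal_window = tuple(self.distal_window)
        self.dual_echo_slab = tuple(self.dual_echo_slab)
        self.sweep_grid = tuple(self.sweep_grid)

    def validate(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.lesion_threshold <= 0:
            raise ValueError("lesion_threshold must be > 0")
        for name, (lo, hi) in (
            ("proximal_window", self.proximal_window),
            ("distal_window", self.distal_window),
        ):
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 1 <= lo <= hi")
        if self.side_aggregation not in ("mean", "sum"):
            raise ValueError(f"unknown side_aggregation {self.side_aggregation!r}")
        if not (self.te2_ms > self.te1_ms > 0):
            raise ValueError("echo times must satisfy te2 > te1 > 0")


# ---------------------------------------------------------------------------
# flat key-value round-tripping


def _flatten(prefix: str, obj: Any, out: dict[str, Any]) -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _flatten(f"{prefix}{k}." if prefix else f"{k}.", v, out)
        return
    key = prefix[:-1]  # drop trailing dot
    if isinstance(obj, tuple):
        obj = list(obj)
    out[key] = obj


def _unflatten(flat: dict[str, Any]) -> dict[str, Any]:
    nested: dict[str, Any] = {}
    for key, value in flat.items():
        parts = key.split(".")
        cur = nested
        for p in parts[:-1]:
            cur = cur.setdefault(p, {})
        cur[parts[-1]] = value
    return nested


def config_to_dict(config: CohortConfig | AnalysisConfig) -> dict[str, Any]:
    """Flatten a config into a single-level ``dotted.key -> value`` mapping."""
    out: dict[str, Any] = {}
    _flatten("", dataclasses.asdict(config), out)
    return out


def save_config(config: CohortConfig | AnalysisConfig, path: str | Path) -> None:
    flat = config_to_dict(config)
    text = yaml.safe_dump(flat, sort_keys=True, default_flow_style=True)
    Path(path).write_text(text)


def _load(cls, path: str | Path):
    flat = yaml.safe_load(Path(path).read_text()) or {}
    nested = _unflatten(flat)
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(nested) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cls(**nested)


def load_cohort_config(path: str | Path) -> CohortConfig:
    """Read a :class:`CohortConfig` from a flat key-value file."""
    return _load(CohortConfig, path)


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a flat key-value file."""
    return _load(AnalysisConfig, path)
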