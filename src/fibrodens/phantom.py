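"""Synthetic murine thoracic-CT phantom generator.

Emulates the densitometric trajectory of radiation-induced pulmonary
fibrosis over 0–20 weeks: two ellipsoidal lungs inside a soft-tissue thorax,
with an increasing fraction of the irradiated lung replaced by patchy
consolidation.  Voxel HU values are drawn from a two-component Gaussian
mixture (aerated parenchyma vs. consolidated tissue), so every downstream
densitometric readout has a closed-form expectation:

    P(HU >= T) = f * Phi((mu_c - T)/sigma_c) + (1 - f) * Phi((mu_a - T)/sigma_a)

where ``f`` is the consolidation fraction and Phi the standard normal
upper-tail.  The default calibration places the week-16 mixture symmetric
about -200 HU, reproducing the canonical landmarks: median HU ~ -500 and
V(-200) < 5% in normal lung, V(-200) < 10% at 12 weeks, HU50 ~ -200 with
V(-200) ~ 50% at 16 weeks, and near-total opacification at 20 weeks.

The generator also emits full cohort tables (slide-level histology grades,
survival, baseline-anchored assay timecourses) so the comparative statistics
layer can be exercised end to end with no external data.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .image import HU_MAX, HU_MIN, LEFT_LUNG, RIGHT_LUNG, LungMask, VoxelVolume, write_mask, write_volume


class GeometryError(ValueError):
    """Raised when the requested grid cannot contain the thorax geometry."""


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureParams:
    """Two-component Gaussian HU mixture for lung parenchyma.

    Aerated parenchyma sits near -500 HU; fibrotic consolidation (thickened
    alveolar walls, collapsed airspace) near +100 HU, soft-tissue range.
    Default spreads are chosen so that a half-consolidated lung is symmetric
    about the -200 HU fibrosis threshold.
    """

    mu_aerated: float = -500.0
    sigma_aerated: float = 100.0
    mu_consolidated: float = 100.0
    sigma_consolidated: float = 100.0

    def __post_init__(self) -> None:
        if self.sigma_aerated <= 0 or self.sigma_consolidated <= 0:
            raise ValueError("mixture sigmas must be positive")
        if self.mu_consolidated <= self.mu_aerated:
            raise ValueError("consolidated mean must exceed aerated mean")

    def tail_fraction(self, threshold: float, f: float) -> float:
        """Analytic P(HU >= threshold) for consolidation fraction ``f``."""
        from scipy.stats import norm

        return float(
            f * norm.sf(threshold, self.mu_consolidated, self.sigma_consolidated)
            + (1.0 - f) * norm.sf(threshold, self.mu_aerated, self.sigma_aerated)
        )


@dataclass(frozen=True)
class StageParams:
    """Fibrosis stage at one post-irradiation timepoint."""

    week: int = 0
    consolidation_fraction: float = 0.0
    n_patch_seeds: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.consolidation_fraction <= 1.0:
            raise ValueError("consolidation_fraction must be in [0, 1]")
        if self.n_patch_seeds < 1:
            raise ValueError("n_patch_seeds must be >= 1")


#: Default consolidation fraction per post-irradiation week, calibrated so
#: that the densitometric landmarks above hold on the irradiated lung.
DEFAULT_STAGE_TABLE: dict[int, float] = {0: 0.0, 8: 0.03, 12: 0.08, 16: 0.50, 20: 0.95}


def stage_for_week(week: int, n_patch_seeds: int = 5) -> StageParams:
    """Look up the default stage for a study week."""
    if week not in DEFAULT_STAGE_TABLE:
        raise KeyError(f"no default stage for week {week}; known: {sorted(DEFAULT_STAGE_TABLE)}")
    return StageParams(week=week, consolidation_fraction=DEFAULT_STAGE_TABLE[week],
                       n_patch_seeds=n_patch_seeds)


@dataclass(frozen=True)
class PhantomConfig:
    """Full specification of one synthetic thoracic CT scan."""

    grid_shape: tuple[int, int, int] = (128, 128, 96)
    spacing_mm: tuple[float, float, float] = (0.25, 0.25, 0.25)
    mixture: MixtureParams = field(default_factory=MixtureParams)
    stage: StageParams = field(default_factory=StageParams)
    irradiated_side: str = "right"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) != n or n < 32 for n in self.grid_shape):
            raise GeometryError(
                f"grid_shape must be 3 integers, each >= 32 voxels, got {self.grid_shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")
        if self.irradiated_side not in ("right", "left", "both"):
            raise ValueError("irradiated_side must be 'right', 'left' or 'both'")

    @property
    def irradiated_labels(self) -> tuple[int, ...]:
        return {"right": (RIGHT_LUNG,), "left": (LEFT_LUNG,),
                "both": (RIGHT_LUNG, LEFT_LUNG)}[self.irradiated_side]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

#: HU of background air and of the soft-tissue thorax cylinder.
AIR_HU = -1000.0
BODY_HU = 40.0

# proportions of the grid occupied by body and lungs; chosen so both lung
# ellipsoids provably fit inside the elliptical body cross-section
_BODY_SEMI = (0.48, 0.45)           # x, y semi-axes as fraction of grid
_LUNG_SEMI = (0.19, 0.22, 0.40)     # per-lung ellipsoid semi-axes
_LUNG_CX = (0.25, 0.75)             # lung centres along x (right, left)


def generate_lung_geometry(config: PhantomConfig) -> tuple[VoxelVolume, LungMask]:
    """Build the deterministic thorax: air background, soft-tissue body,
    two ellipsoidal lung fields.

    Returns the baseline HU volume (lungs filled uniformly at the aerated
    mean, to be stochastically rendered later) and the label mask
    (1 = right lung, 2 = left lung).
    """
    nx, ny, nz = (int(n) for n in config.grid_shape)
    ax, ay = _BODY_SEMI[0] * nx, _BODY_SEMI[1] * ny
    lx, ly, lz = _LUNG_SEMI[0] * nx, _LUNG_SEMI[1] * ny, _LUNG_SEMI[2] * nz
    cx_body, cy_body, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0

    # analytic fit check: extreme lung point along x must be inside the body
    for cfrac in _LUNG_CX:
        cx = cfrac * nx
        reach = abs(cx - cx_body) + lx
        if reach >= ax or ly >= ay or lz > nz / 2.0:
            raise GeometryError(
                f"grid {config.grid_shape} too small to contain two lung ellipsoids")

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij", sparse=True)
    body = ((ii - cx_body) / ax) ** 2 + ((jj - cy_body) / ay) ** 2 <= 1.0
    body = np.broadcast_to(body, (nx, ny, nz))

    mask = np.zeros((nx, ny, nz), dtype=np.uint8)
    for label, cfrac in ((RIGHT_LUNG, _LUNG_CX[0]), (LEFT_LUNG, _LUNG_CX[1])):
        cx = cfrac * nx
        lung = (((ii - cx) / lx) ** 2 + ((jj - cy_body) / ly) ** 2
                + ((kk - cz) / lz) ** 2) <= 1.0
        if not lung.any():
            raise GeometryError("lung ellipsoid contains no voxels")
        mask[lung] = label

    hu = np.full((nx, ny, nz), AIR_HU, dtype=np.float32)
    hu[body] = BODY_HU
    hu[mask > 0] = config.mixture.mu_aerated

    spacing = config.spacing_mm
    return VoxelVolume(hu, spacing), LungMask(mask, spacing)


# ---------------------------------------------------------------------------
# consolidation growth
# ---------------------------------------------------------------------------

def grow_consolidation(mask: LungMask, side: int, f: float, n_seeds: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Grow patchy consolidation covering exactly ``ceil(f * N)`` voxels of
    the target lung.

    Seeds are sampled uniformly over the lung; regions grow voxel-by-voxel
    by 6-connectivity with the frontier voxel chosen at random, yielding a
    union of at most ``n_seeds`` connected blobs.  The flagged set is always
    a subset of the target lung and its size is exact for any ``f``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"consolidation fraction must be in [0, 1], got {f}")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    lung = mask.data == side
    n_lung = int(lung.sum())
    if n_lung == 0:
        raise ValueError(f"label {side} absent from mask")

    target = math.ceil(f * n_lung)
    flags = np.zeros(mask.shape, dtype=bool)
    if target == 0:
        return flags
    if target == n_lung:
        return lung.copy()

    nx, ny, nz = mask.shape
    strides = (ny * nz, nz, 1)
    lung_flat = lung.ravel()
    flags_flat = flags.ravel()
    lung_idx = np.flatnonzero(lung_flat)

    seeds = rng.choice(lung_idx, size=min(n_seeds, n_lung), replace=False)
    frontier: list[int] = [int(s) for s in seeds]
    flagged = 0
    while flagged < target:
        if not frontier:
            # disconnected remainder: re-seed uniformly among unflagged lung
            remaining = lung_idx[~flags_flat[lung_idx]]
            frontier.append(int(rng.choice(remaining)))
        pick = int(rng.integers(len(frontier)))
        frontier[pick], frontier[-1] = frontier[-1], frontier[pick]
        idx = frontier.pop()
        if flags_flat[idx]:
            continue
        flags_flat[idx] = True
        flagged += 1
        i, rem = divmod(idx, strides[0])
        j, k = divmod(rem, strides[1])
        if i > 0 and lung_flat[idx - strides[0]] and not flags_flat[idx - strides[0]]:
            frontier.append(idx - strides[0])
        if i < nx - 1 and lung_flat[idx + strides[0]] and not flags_flat[idx + strides[0]]:
            frontier.append(idx + strides[0])
        if j > 0 and lung_flat[idx - strides[1]] and not flags_flat[idx - strides[1]]:
            frontier.append(idx - strides[1])
        if j < ny - 1 and lung_flat[idx + strides[1]] and not flags_flat[idx + strides[1]]:
            frontier.append(idx + strides[1])
        if k > 0 and lung_flat[idx - 1] and not flags_flat[idx - 1]:
            frontier.append(idx - 1)
        if k < nz - 1 and lung_flat[idx + 1] and not flags_flat[idx + 1]:
            frontier.append(idx + 1)
    return flags


# ---------------------------------------------------------------------------
# HU rendering
# ---------------------------------------------------------------------------

def render_hu(geometry: VoxelVolume, mask: LungMask, consolidation: np.ndarray,
              mixture: MixtureParams, rng: np.random.Generator) -> VoxelVolume:
    """Draw stochastic HU values for lung voxels over the geometry baseline.

    Aerated lung voxels are iid Normal(mu_aerated, sigma_aerated);
    consolidated voxels iid Normal(mu_consolidated, sigma_consolidated);
    everything is clamped to the 12-bit CT range [-1024, 3071].  Non-lung
    voxels are returned unchanged.
    """
    if geometry.shape != mask.shape or consolidation.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: geometry {geometry.shape}, mask {mask.shape}, "
            f"consolidation {consolidation.shape}")
    lung = mask.data > 0
    aerated = lung & ~consolidation
    consolidated = lung & consolidation

    hu = geometry.data.copy()
    n_a, n_c = int(aerated.sum()), int(consolidated.sum())
    if n_a:
        hu[aerated] = rng.normal(mixture.mu_aerated, mixture.sigma_aerated, size=n_a)
    if n_c:
        hu[consolidated] = rng.normal(mixture.mu_consolidated,
                                      mixture.sigma_consolidated, size=n_c)
    np.clip(hu, HU_MIN, HU_MAX, out=hu)
    return VoxelVolume(hu, geometry.spacing_mm)


def generate_phantom(config: PhantomConfig) -> tuple[VoxelVolume, LungMask]:
    """Generate a complete stage phantom: geometry, consolidation growth on
    the irradiated side(s), stochastic HU rendering.  Bit-reproducible for a
    fixed config (seed included)."""
    rng = np.random.default_rng(config.rng_seed)
    geometry, mask = generate_lung_geometry(config)
    consolidation = np.zeros(mask.shape, dtype=bool)
    for label in config.irradiated_labels:
        consolidation |= grow_consolidation(
            mask, label, config.stage.consolidation_fraction,
            config.stage.n_patch_seeds, rng)
    volume = render_hu(geometry, mask, consolidation, config.mixture, rng)
    return volume, mask


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One study arm: a drug group names its matched vehicle; a vehicle
    group leaves ``matched_vehicle`` empty."""

    name: str
    treatment: str
    matched_vehicle: str = ""
    n_animals: int = 10

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


#: Default assay mean trajectories (relative to day 0) for the timecourse
#: tables: ligand and receptor expression rising after lung injury.
DEFAULT_ASSAY_TRAJECTORIES: dict[str, dict[int, float]] = {
    "CXCL12_BALF": {0: 1.0, 1: 1.1, 3: 1.4, 7: 1.9, 14: 2.6, 28: 3.2},
    "CXCR4_mRNA": {0: 1.0, 1: 1.0, 3: 1.3, 7: 1.7, 14: 2.2, 28: 2.8},
}

ASSAY_DAYS = (0, 1, 3, 7, 14, 28)


@dataclass
class CohortConfig:
    """Study design for a full synthetic cohort.

    Defaults mirror a two-antagonist hemithoracic-irradiation study: two
    drug arms (daily AMD3100 s.c., daily MSX-122 i.p.) each with a matched
    vehicle arm (PBS s.c.; 10% DMSO / 45% cyclodextrin i.p.), n = 10 per
    group, endpoint at 20 weeks.  Drug efficacy enters through a scaled
    consolidation fraction; mortality through a per-study death probability.
    """

    groups: list[GroupSpec] = field(default_factory=lambda: [
        GroupSpec("vehicle_pbs", "PBS s.c.", "", 10),
        GroupSpec("vehicle_dmso_cd", "10% DMSO / 45% CD i.p.", "", 10),
        GroupSpec("amd3100", "AMD3100 10 mg/kg s.c.", "vehicle_pbs", 10),
        GroupSpec("msx122", "MSX-122 10 mg/kg i.p.", "vehicle_dmso_cd", 10),
    ])
    timepoints: list[int] = field(default_factory=lambda: [20])
    #: fibrosis attenuation per group: consolidation fraction multiplier
    stage_scale_by_group: dict[str, float] = field(default_factory=lambda: {
        "vehicle_pbs": 1.0, "vehicle_dmso_cd": 1.0,
        "amd3100": 0.8, "msx122": 0.3,
    })
    stage_by_group_week: dict[tuple[str, int], StageParams] = field(default_factory=dict)
    histology_noise_sd: float = 0.5
    mortality_prob_by_group: dict[str, float] = field(default_factory=lambda: {
        "vehicle_pbs": 0.0, "vehicle_dmso_cd": 0.0, "amd3100": 0.5, "msx122": 0.0,
    })
    assay_trajectories: dict[str, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ASSAY_TRAJECTORIES.items()})
    assay_noise_cv: float = 0.10
    assay_replicates: int = 3
    grid_shape: tuple[int, int, int] = (128, 128, 96)
    spacing_mm: tuple[float, float, float] = (0.25, 0.25, 0.25)
    mixture: MixtureParams = field(default_factory=MixtureParams)
    irradiated_side: str = "right"
    write_volumes: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.histology_noise_sd < 0:
            raise ValueError("histology_noise_sd must be >= 0")
        names = {g.name for g in self.groups}
        for g in self.groups:
            if g.matched_vehicle and g.matched_vehicle not in names:
                raise ValueError(
                    f"group {g.name!r} names unknown vehicle {g.matched_vehicle!r}")

    def stage_for(self, group: str, week: int) -> StageParams:
        """Stage for one group x week: explicit table first, else the default
        week table scaled by the group's attenuation factor."""
        if (group, week) in self.stage_by_group_week:
            return self.stage_by_group_week[(group, week)]
        base = DEFAULT_STAGE_TABLE.get(week)
        if base is None:
            raise KeyError(f"no stage defined for group {group!r} week {week}")
        scale = self.stage_scale_by_group.get(group, 1.0)
        return StageParams(week=week, consolidation_fraction=min(1.0, base * scale))


def sample_histology_grades(f: float, noise_sd: float,
                            rng: np.random.Generator, n_slides: int = 3) -> list[int]:
    """Slide grades 0-4 linked to consolidation fraction:
    grade = clamp(round(4 f + Normal(0, sd)), 0, 4), one draw per slide."""
    raw = 4.0 * f + rng.normal(0.0, noise_sd, size=n_slides) if noise_sd > 0 \
        else np.full(n_slides, 4.0 * f)
    return [int(np.clip(np.rint(g), 0, 4)) for g in raw]


def sample_survival(groups: list[GroupSpec], mortality_prob_by_group: dict[str, float],
                    horizon_week: int, rng: np.random.Generator) -> list[dict]:
    """Per-animal death indicator (Bernoulli per-study probability); dead
    animals get a uniform death week in [1, horizon]."""
    rows = []
    for g in groups:
        p = mortality_prob_by_group.get(g.name, 0.0)
        for i in range(g.n_animals):
            dead = bool(rng.random() < p)
            rows.append({
                "animal_id": f"{g.name}-{i + 1:02d}",
                "group": g.name,
                "death_week": int(rng.integers(1, horizon_week + 1)) if dead else None,
            })
    return rows


def generate_cohort(config: CohortConfig, out_dir: str | os.PathLike) -> dict:
    """Generate the full cohort bundle on disk.

    Writes per-animal per-timepoint CT volumes and masks (NIfTI), plus
    ``histology.csv`` (3 slide grades per animal per week), ``survival.csv``
    (death week or empty), ``timecourse.csv`` (replicate assay values per
    day), and a ``manifest.json`` listing every file and the seed.

    Returns the manifest as a dict.
    """
    import pandas as pd

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    horizon = max(config.timepoints) if config.timepoints else 20

    volume_files: list[str] = []
    histology_rows: list[dict] = []
    for g in config.groups:
        for week in config.timepoints:
            stage = config.stage_for(g.name, week)
            for i in range(g.n_animals):
                animal_id = f"{g.name}-{i + 1:02d}"
                if config.write_volumes:
                    seed = int(rng.integers(0, 2**31 - 1))
                    pc = PhantomConfig(
                        grid_shape=config.grid_shape, spacing_mm=config.spacing_mm,
                        mixture=config.mixture, stage=stage,
                        irradiated_side=config.irradiated_side, rng_seed=seed)
                    vol, msk = generate_phantom(pc)
                    vpath = os.path.join(out_dir, f"{animal_id}_w{week}_ct.nii.gz")
                    mpath = os.path.join(out_dir, f"{animal_id}_w{week}_mask.nii.gz")
                    write_volume(vol, vpath)
                    write_mask(msk, mpath)
                    volume_files += [os.path.basename(vpath), os.path.basename(mpath)]
                g1, g2, g3 = sample_histology_grades(
                    stage.consolidation_fraction, config.histology_noise_sd, rng)
                histology_rows.append({
                    "animal_id": animal_id, "group": g.name, "week": week,
                    "slide1": g1, "slide2": g2, "slide3": g3,
                })

    survival_rows = sample_survival(config.groups, config.mortality_prob_by_group,
                                    horizon, rng)
    timecourse_rows: list[dict] = []
    for assay, traj in config.assay_trajectories.items():
        for day in ASSAY_DAYS:
            mean = traj.get(day)
            if mean is None:
                continue
            sd = abs(mean) * config.assay_noise_cv
            for r in range(config.assay_replicates):
                val = float(rng.normal(mean, sd)) if sd > 0 else float(mean)
                timecourse_rows.append({
                    "assay": assay, "day": day,
                    "animal_id": f"tc-{r + 1:02d}", "value": val,
                })

    hist_df = pd.DataFrame(histology_rows)
    surv_df = pd.DataFrame(survival_rows)
    surv_df["death_week"] = surv_df["death_week"].astype("Int64")
    tc_df = pd.DataFrame(timecourse_rows)
    hist_df.to_csv(os.path.join(out_dir, "histology.csv"), index=False)
    surv_df.to_csv(os.path.join(out_dir, "survival.csv"), index=False)
    tc_df.to_csv(os.path.join(out_dir, "timecourse.csv"), index=False)

    pairing = {g.name: g.matched_vehicle for g in config.groups if g.matched_vehicle}
    with open(os.path.join(out_dir, "pairing.json"), "w") as fh:
        json.dump(pairing, fh, indent=2)

    manifest = {
        "seed": config.rng_seed,
        "groups": [dataclasses.asdict(g) for g in config.groups],
        "timepoints": list(config.timepoints),
        "files": sorted(volume_files + ["histology.csv", "survival.csv",
                                        "timecourse.csv", "pairing.json"]),
        "n_volumes": len(volume_files) // 2,
        "n_histology_rows": len(hist_df),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
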