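"""Synthetic atlases, gray-matter priors, and tau cohorts.

The generator emulates the *inputs* of the pipeline, not tau biology: a
phantom atlas of disjoint cuboid regions on a regular lattice (each large
enough to host a 3x3x3 node cube), a gray-matter prior of 1.0 inside the
regions, and per-subject regional SUVR profiles following an additive hinge
model of graded accumulation,

    mean_r(s) = baseline + amplitude_tier(r) * max(0, s - onset_tier(r)) + noise,

where the subject's scalar severity s ~ U(0,1) and the tier onsets are
ordered limbic < temporal < isocortical (off-target regions never
elevate), mimicking the canonical medial-temporal-to-isocortex spread of
neurofibrillary tau. Amplitudes and onsets default to values that make a
64-region cohort's limbic strengths straddle the fixed staging thresholds.

Rendering a profile back into a voxel image (region voxels = regional mean
+ voxel noise, background at a non-specific level) closes the loop so the
whole pipeline can be exercised end-to-end without any real scan.

Every operation takes an explicit seed; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .imaging import LabelImage, VoxelImage
from .nodes import RegionalProfile

__all__ = [
    "PhantomAtlas",
    "SimulationConfig",
    "make_phantom_atlas",
    "simulate_profiles",
    "render_image",
]

TIERS = ("limbic", "temporal", "isocortical", "off-target")


@dataclass
class PhantomAtlas:
    labels: LabelImage
    gm_prob: VoxelImage
    region_tiers: dict[int, str]

    @property
    def region_ids(self) -> list[int]:
        return self.labels.region_ids

    def tier_ids(self, tier: str) -> list[int]:
        return [r for r, t in self.region_tiers.items() if t == tier]

    @property
    def limbic_ids(self) -> list[int]:
        return self.tier_ids("limbic")


@dataclass
class SimulationConfig:
    """Cohort generation parameters (SUVR units unless noted).

    Defaults describe a mildly noisy cohort whose severity gradient drives
    limbic-first accumulation; see the package docs for the rationale.
    """

    n_subjects: int = 50
    baseline_mean: float = 1.1
    baseline_sd: float = 0.05
    onsets: dict[str, float] = field(
        default_factory=lambda: {
            "limbic": 0.0,
            "temporal": 0.30,
            "isocortical": 0.55,
            "off-target": np.inf,
        }
    )
    amplitudes: dict[str, float] = field(
        default_factory=lambda: {
            "limbic": 0.9,
            "temporal": 0.55,
            "isocortical": 0.35,
            "off-target": 0.0,
        }
    )
    noise_sd: float = 0.02  # regional measurement noise
    seed: int = 0

    def __post_init__(self) -> None:
        on = self.onsets
        if not on["limbic"] < on["temporal"] < on["isocortical"]:
            raise ValueError("tier onsets must be strictly ordered limbic < temporal < isocortical")
        if self.baseline_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


def make_phantom_atlas(
    grid: Sequence[int] = (48, 48, 48),
    k: int = 8,
    region_size: int = 5,
    gm_background: float = 0.0,
    spacing_mm: float = 2.0,
    seed: int = 0,
) -> PhantomAtlas:
    """Pack k disjoint cuboid regions onto a lattice, with a GM prior of 1
    inside every region.

    Regions are laid out on a regular 3-D lattice of cells with at least one
    voxel of margin between neighbours, in a seed-deterministic order, and
    tiers are assigned round-robin starting with four limbic regions (the
    limbic-strength definition wants bilateral amygdala + parahippocampal,
    i.e. four nodes).
    """
    grid = tuple(int(g) for g in grid)
    if region_size < 3:
        raise ValueError("regions must be at least 3 voxels per side to host a cube")
    cell = region_size + 2  # 1-voxel margin on each side
    per_axis = tuple(g // cell for g in grid)
    capacity = int(np.prod(per_axis))
    if capacity < k:
        raise ValueError(
            f"grid {grid} can host at most {capacity} regions of size {region_size}; asked for {k}"
        )
    rng = np.random.default_rng(seed)
    cells = [
        (i, j, l)
        for i in range(per_axis[0])
        for j in range(per_axis[1])
        for l in range(per_axis[2])
    ]
    chosen = [cells[i] for i in rng.choice(len(cells), size=k, replace=False)]

    labels = np.zeros(grid, dtype=np.int32)
    names: dict[int, str] = {}
    tiers: dict[int, str] = {}
    # four limbic first, then temporal/isocortical alternating, last region
    # off-target when k is large enough to afford one
    tier_plan: list[str] = []
    for idx in range(k):
        if idx < min(4, k):
            tier_plan.append("limbic")
        elif k >= 6 and idx == k - 1:
            tier_plan.append("off-target")
        else:
            tier_plan.append("temporal" if (idx % 2 == 0) else "isocortical")
    for rid, (ci, cj, cl) in enumerate(chosen, start=1):
        x0, y0, z0 = ci * cell + 1, cj * cell + 1, cl * cell + 1
        labels[x0 : x0 + region_size, y0 : y0 + region_size, z0 : z0 + region_size] = rid
        tiers[rid] = tier_plan[rid - 1]
        names[rid] = f"{tier_plan[rid - 1]}_{rid}"
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    gm = np.full(grid, gm_background, dtype=float)
    gm[labels > 0] = 1.0
    return PhantomAtlas(
        labels=LabelImage(labels=labels, affine=affine, names=names),
        gm_prob=VoxelImage(values=gm, affine=affine),
        region_tiers=tiers,
    )


def simulate_profiles(
    atlas: PhantomAtlas, config: SimulationConfig
) -> tuple[list[RegionalProfile], np.ndarray]:
    """Draw a cohort of regional profiles; returns (profiles, severities)."""
    rng = np.random.default_rng(config.seed)
    rids = atlas.region_ids
    severities = rng.uniform(0.0, 1.0, size=config.n_subjects)
    profiles = []
    for i, s in enumerate(severities):
        baseline = config.baseline_mean + rng.normal(0.0, config.baseline_sd)
        values = np.empty(len(rids))
        for j, rid in enumerate(rids):
            tier = atlas.region_tiers[rid]
            onset = config.onsets[tier]
            amp = config.amplitudes[tier]
            hinge = amp * max(0.0, s - onset) if np.isfinite(onset) else 0.0
            values[j] = baseline + hinge + rng.normal(0.0, config.noise_sd)
        profiles.append(
            RegionalProfile(subject_id=f"sim{i:03d}", node_ids=list(rids), values=values)
        )
    return profiles, severities


def render_image(
    profile: RegionalProfile,
    atlas: PhantomAtlas,
    voxel_noise_sd: float = 0.0,
    background: float = 0.9,
    seed: int = 0,
) -> VoxelImage:
    """Paint a regional profile into a voxel image on the phantom grid.

    Region voxels get the regional mean plus independent Gaussian voxel
    noise; everything else sits at a non-specific background level.
    """
    rids = atlas.region_ids
    if list(profile.node_ids) != rids:
        raise ValueError(
            f"profile node ids {profile.node_ids} do not match atlas regions {rids}"
        )
    rng = np.random.default_rng(seed)
    labels = atlas.labels.labels
    img = np.full(labels.shape, float(background))
    for rid, mean in zip(rids, profile.values):
        mask = labels == rid
        img[mask] = mean
    if voxel_noise_sd > 0:
        img = img + rng.normal(0.0, voxel_noise_sd, size=img.shape)
    return VoxelImage(values=img, affine=atlas.labels.affine, is_suvr=True)
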