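"""Cube-node definition and per-subject regional profile extraction.

Each atlas region contributes one candidate node: a 6-mm cube at the
region's center, realised as a 3x3x3 block of 2-mm voxels (edge and spacing
configurable). A node enters the network only if

a) all of its cube voxels survive the binarized gray-matter mask, and
b) its cube overlaps no other region's cube (both members of an overlapping
   pair are dropped — symmetric, hence independent of enumeration order).

The region "center" is the voxel nearest the region's center of mass in
voxel units, with a lexicographic tie-break, which makes selection fully
deterministic. The node value of a subject is the arithmetic mean SUVR over
the cube's voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .imaging import LabelImage, VoxelImage, _check_geometry

__all__ = [
    "NodeDefinition",
    "NodeSet",
    "RegionalProfile",
    "binarize_gm",
    "region_center",
    "cube_voxels",
    "select_nodes",
    "extract_profile",
]

EXCLUSION_REASONS = ("none", "overlap", "gm_coverage", "region_missing")


@dataclass
class NodeDefinition:
    region_id: int
    name: str
    center: tuple[int, int, int] | None
    cube_voxels: np.ndarray | None  # (edge^3, 3) int array, or None if region missing
    included: bool
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")
        if self.included and self.exclusion_reason != "none":
            raise ValueError("included node cannot carry an exclusion reason")


@dataclass
class NodeSet:
    """Ordered node definitions plus the ids used for limbic strength."""

    nodes: list[NodeDefinition]
    limbic_ids: frozenset[int] = frozenset()
    grid_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    cube_edge: int = 3

    @property
    def included(self) -> list[NodeDefinition]:
        return [n for n in self.nodes if n.included]

    @property
    def included_ids(self) -> list[int]:
        return [n.region_id for n in self.included]

    def exclusion_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in EXCLUSION_REASONS if r != "none"}
        for n in self.nodes:
            if not n.included:
                counts[n.exclusion_reason] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n in self.nodes:
            cx, cy, cz = n.center if n.center is not None else (-1, -1, -1)
            rows.append(
                dict(
                    region_id=n.region_id,
                    name=n.name,
                    center_x=cx,
                    center_y=cy,
                    center_z=cz,
                    included=n.included,
                    exclusion_reason=n.exclusion_reason,
                )
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


@dataclass
class RegionalProfile:
    """Per-subject node-mean SUVRs, ordered like the NodeSet."""

    subject_id: str
    node_ids: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.node_ids) != self.values.size:
            raise ValueError("profile values must be a vector matching node_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"profile for {self.subject_id} contains non-finite values")


def binarize_gm(prob_map: VoxelImage, threshold: float = 0.3) -> np.ndarray:
    """Binarize a probabilistic gray-matter map at `threshold` (inclusive >=)."""
    vals = np.asarray(prob_map.values, dtype=float)
    if vals.min() < -1e-6 or vals.max() > 1 + 1e-6:
        raise ValueError(
            f"gray-matter probabilities must lie in [0,1]; got range "
            f"[{vals.min():.4g}, {vals.max():.4g}]"
        )
    return (vals >= threshold).astype(np.uint8)


def region_center(labels: LabelImage, region_id: int) -> tuple[int, int, int]:
    """Voxel nearest (Euclidean, voxel units) to the region's center of mass.

    Ties are broken by lexicographic (x, y, z) order of the voxel coordinate.
    """
    coords = np.argwhere(labels.labels == region_id)
    if coords.size == 0:
        raise ValueError(f"region {region_id} has no voxels")
    com = coords.mean(axis=0)
    d2 = ((coords - com) ** 2).sum(axis=1)
    best = d2.min()
    candidates = coords[d2 <= best + 1e-12]
    order = np.lexsort((candidates[:, 2], candidates[:, 1], candidates[:, 0]))
    cx, cy, cz = candidates[order[0]]
    return int(cx), int(cy), int(cz)


def cube_voxels(
    center: Sequence[int], edge: int = 3, shape: Sequence[int] | None = None
) -> tuple[np.ndarray, bool]:
    """The edge^3 voxel coordinates of an axis-aligned cube at `center`.

    Returns ``(coords, in_bounds)``; out-of-bounds cubes are returned intact
    so the caller can record the exclusion.
    """
    if edge < 1 or edge % 2 == 0:
        raise ValueError(f"cube edge must be an odd positive integer, got {edge}")
    half = (edge - 1) // 2
    c = np.asarray(center, dtype=int)
    offs = np.arange(-half, half + 1)
    grid = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1).reshape(-1, 3)
    coords = c[None, :] + grid
    in_bounds = True
    if shape is not None:
        shape_arr = np.asarray(shape, dtype=int)
        in_bounds = bool(np.all(coords >= 0) and np.all(coords < shape_arr[None, :]))
    return coords, in_bounds


def select_nodes(
    labels: LabelImage,
    gm_mask: np.ndarray,
    cube_edge: int = 3,
    limbic_ids: Iterable[int] = (),
    include_list: Iterable[int] | None = None,
    expected_spacing: float = 2.0,
) -> NodeSet:
    """Apply the gray-matter and independence rules to every atlas region.

    A candidate is dropped with reason ``gm_coverage`` if any cube voxel
    falls outside the image or outside the binarized gray-matter mask, and
    with reason ``overlap`` if its cube shares a voxel with any other
    region's cube (both members of the pair are dropped). ``include_list``,
    when given, overrides rule-based selection with an explicit set of
    region ids (regions absent from it are marked excluded with their
    rule-based reason, or ``none`` replaced by ``overlap``-free bookkeeping).
    """
    gm_mask = np.asarray(gm_mask)
    if gm_mask.shape != labels.shape:
        raise ValueError(
            f"gray-matter mask shape {gm_mask.shape} does not match atlas {labels.shape}"
        )
    region_ids = labels.region_ids
    if not region_ids:
        raise ValueError("atlas contains no positive region labels")

    spacing = np.sqrt((np.asarray(labels.affine)[:3, :3] ** 2).sum(axis=0))
    if not np.allclose(spacing, expected_spacing, atol=1e-3):
        cube_mm = tuple(float(s) * cube_edge for s in spacing)
        warnings.warn(
            f"grid spacing {tuple(np.round(spacing, 3))} mm differs from the "
            f"expected {expected_spacing} mm; physical cube size is {cube_mm} mm",
            stacklevel=2,
        )

    # first pass: centers, cubes, gray-matter coverage
    cubes: dict[int, np.ndarray] = {}
    gm_ok: dict[int, bool] = {}
    centers: dict[int, tuple[int, int, int]] = {}
    for rid in region_ids:
        center = region_center(labels, rid)
        coords, in_bounds = cube_voxels(center, cube_edge, labels.shape)
        centers[rid] = center
        cubes[rid] = coords
        if not in_bounds:
            gm_ok[rid] = False
        else:
            gm_ok[rid] = bool(np.all(gm_mask[coords[:, 0], coords[:, 1], coords[:, 2]] > 0))

    # second pass: pairwise overlap against ALL other regions' cubes
    voxel_owner: dict[tuple[int, int, int], list[int]] = {}
    for rid in region_ids:
        for v in map(tuple, cubes[rid]):
            voxel_owner.setdefault(v, []).append(rid)
    overlapping: set[int] = set()
    for owners in voxel_owner.values():
        if len(owners) > 1:
            overlapping.update(owners)

    explicit = set(include_list) if include_list is not None else None
    nodes: list[NodeDefinition] = []
    for rid in sorted(region_ids):
        if explicit is not None:
            included = rid in explicit
            reason = "none" if included else "region_missing"
            if included and not gm_ok[rid]:
                # explicit include still needs a geometrically valid cube
                included, reason = False, "gm_coverage"
        else:
            if not gm_ok[rid]:
                included, reason = False, "gm_coverage"
            elif rid in overlapping:
                included, reason = False, "overlap"
            else:
                included, reason = True, "none"
        nodes.append(
            NodeDefinition(
                region_id=rid,
                name=labels.names.get(rid, f"region_{rid}"),
                center=centers[rid],
                cube_voxels=cubes[rid],
                included=included,
                exclusion_reason=reason,
            )
        )
    return NodeSet(
        nodes=nodes,
        limbic_ids=frozenset(int(i) for i in limbic_ids),
        grid_spacing=tuple(float(s) for s in spacing),
        cube_edge=cube_edge,
    )


def extract_profile(
    suvr: VoxelImage, node_set: NodeSet, subject_id: str = ""
) -> RegionalProfile:
    """Mean SUVR over each included node's cube voxels."""
    means = []
    ids = []
    for node in node_set.included:
        coords = node.cube_voxels
        if coords is None or np.any(coords < 0) or np.any(
            coords >= np.asarray(suvr.shape)[None, :]
        ):
            raise ValueError(
                f"node {node.region_id}: cube does not fit image shape {suvr.shape}"
            )
        vals = suvr.values[coords[:, 0], coords[:, 1], coords[:, 2]]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite voxel inside cube of node {node.region_id}")
        means.append(float(np.mean(vals)))
        ids.append(node.region_id)
    return RegionalProfile(subject_id=subject_id, node_ids=ids, values=np.array(means))
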