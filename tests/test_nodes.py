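import numpy as np
import pytest

from taunet.imaging import LabelImage, VoxelImage
from taunet.nodes import (
    binarize_gm,
    cube_voxels,
    extract_profile,
    region_center,
    select_nodes,
)
from taunet.synthetic import SimulationConfig, render_image, simulate_profiles

AFFINE2MM = np.diag([2.0, 2.0, 2.0, 1.0])


def _gm(values):
    return VoxelImage(values=np.asarray(values, dtype=float), affine=AFFINE2MM)


class TestBinarizeGm:
    def test_threshold_is_inclusive(self):
        probs = np.zeros((2, 2, 2))
        probs[0, 0, 0] = 0.3
        probs[0, 0, 1] = 0.29
        mask = binarize_gm(_gm(probs))
        assert mask[0, 0, 0] == 1
        assert mask[0, 0, 1] == 0

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            binarize_gm(_gm(np.full((2, 2, 2), 1.5)))

    def test_all_zero_map_excludes_every_node(self):
        labels = np.zeros((20, 20, 20), dtype=int)
        labels[4:9, 4:9, 4:9] = 1
        lab = LabelImage(labels=labels, affine=AFFINE2MM)
        ns = select_nodes(lab, binarize_gm(_gm(np.zeros((20, 20, 20)))))
        assert len(ns.included) == 0
        assert ns.nodes[0].exclusion_reason == "gm_coverage"


class TestRegionCenter:
    def _labels(self, mask):
        labels = np.zeros((20, 20, 20), dtype=int)
        labels[mask] = 1
        return LabelImage(labels=labels, affine=AFFINE2MM)

    def test_single_voxel(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[10, 10, 10] = True
        assert region_center(self._labels(mask), 1) == (10, 10, 10)

    def test_solid_block_center(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[0:5, 0:5, 0:5] = True
        assert region_center(self._labels(mask), 1) == (2, 2, 2)

    def test_l_shape_matches_brute_force(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[2:10, 2:4, 2:4] = True
        mask[2:4, 2:10, 2:4] = True
        lab = self._labels(mask)
        coords = np.argwhere(lab.labels == 1)
        com = coords.mean(axis=0)
        d2 = ((coords - com) ** 2).sum(axis=1)
        best = coords[d2 == d2.min()]
        expected = tuple(sorted(map(tuple, best))[0])
        assert region_center(lab, 1) == expected

    def test_empty_region_is_error(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[1, 1, 1] = True
        with pytest.raises(ValueError, match="region 9"):
            region_center(self._labels(mask), 9)


class TestCubeVoxels:
    def test_edge3_spans_centered_cube(self):
        coords, ok = cube_voxels((5, 5, 5), 3, (12, 12, 12))
        assert ok and coords.shape == (27, 3)
        assert coords.min() == 4 and coords.max() == 6
        assert len({tuple(c) for c in coords}) == 27

    def test_edge1_is_the_center(self):
        coords, ok = cube_voxels((5, 5, 5), 1, (12, 12, 12))
        assert ok and coords.tolist() == [[5, 5, 5]]

    def test_even_edge_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            cube_voxels((5, 5, 5), 2, (12, 12, 12))

    def test_boundary_center_detected_out_of_bounds(self):
        _, ok = cube_voxels((0, 5, 5), 3, (12, 12, 12))
        assert not ok


def _atlas_with_centers(centers, shape=(24, 24, 24)):
    """Single-voxel regions at given centers (center of a 1-voxel region is itself)."""
    labels = np.zeros(shape, dtype=int)
    for rid, c in enumerate(centers, start=1):
        labels[c] = rid
    return LabelImage(labels=labels, affine=AFFINE2MM)


class TestSelectNodes:
    def test_well_separated_regions_all_included(self):
        lab = _atlas_with_centers([(5, 5, 5), (15, 15, 15)])
        ns = select_nodes(lab, np.ones(lab.shape, dtype=np.uint8))
        assert [n.included for n in ns.nodes] == [True, True]

    def test_overlapping_cubes_exclude_both(self):
        lab = _atlas_with_centers([(5, 5, 5), (5, 5, 7)])  # cubes share the z=6 plane
        ns = select_nodes(lab, np.ones(lab.shape, dtype=np.uint8))
        assert [n.included for n in ns.nodes] == [False, False]
        assert {n.exclusion_reason for n in ns.nodes} == {"overlap"}

    def test_gm_hole_excludes_with_reason(self):
        lab = _atlas_with_centers([(5, 5, 5), (15, 15, 15)])
        gm = np.ones(lab.shape, dtype=np.uint8)
        gm[6, 5, 5] = 0  # one cube voxel of region 1
        ns = select_nodes(lab, gm)
        assert ns.nodes[0].exclusion_reason == "gm_coverage"
        assert ns.nodes[1].included

    def test_selection_is_permutation_invariant(self):
        centers = [(5, 5, 5), (5, 5, 7), (15, 15, 15), (15, 5, 5)]
        lab = _atlas_with_centers(centers)
        ns = select_nodes(lab, np.ones(lab.shape, dtype=np.uint8))
        # relabel regions in reverse order; inclusion must follow geometry
        relabeled = np.zeros(lab.shape, dtype=int)
        for rid, c in enumerate(reversed(centers), start=1):
            relabeled[c] = rid
        ns2 = select_nodes(
            LabelImage(labels=relabeled, affine=AFFINE2MM),
            np.ones(lab.shape, dtype=np.uint8),
        )
        by_center = {n.center: (n.included, n.exclusion_reason) for n in ns.nodes}
        by_center2 = {n.center: (n.included, n.exclusion_reason) for n in ns2.nodes}
        assert by_center == by_center2

    def test_included_cubes_pairwise_disjoint(self, small_atlas):
        ns = select_nodes(
            small_atlas.labels, binarize_gm(small_atlas.gm_prob)
        )
        seen = set()
        for node in ns.included:
            voxels = {tuple(v) for v in node.cube_voxels}
            assert not (voxels & seen)
            seen |= voxels

    def test_include_list_overrides_rules(self):
        lab = _atlas_with_centers([(5, 5, 5), (5, 5, 7), (15, 15, 15)])
        ns = select_nodes(lab, np.ones(lab.shape, dtype=np.uint8), include_list=[1, 3])
        assert [n.included for n in ns.nodes] == [True, False, True]

    def test_no_regions_is_error(self):
        lab = LabelImage(labels=np.zeros((8, 8, 8), dtype=int), affine=AFFINE2MM)
        with pytest.raises(ValueError, match="no positive region"):
            select_nodes(lab, np.ones((8, 8, 8), dtype=np.uint8))

    def test_non_2mm_grid_warns_not_errors(self):
        labels = np.zeros((24, 24, 24), dtype=int)
        labels[5, 5, 5] = 1
        lab = LabelImage(labels=labels, affine=np.diag([1.5, 1.5, 1.5, 1.0]))
        with pytest.warns(UserWarning, match="cube size"):
            ns = select_nodes(lab, np.ones((24, 24, 24), dtype=np.uint8))
        assert len(ns.nodes) == 1


class TestExtractProfile:
    def test_hand_arithmetic_mean(self):
        lab = _atlas_with_centers([(5, 5, 5)])
        ns = select_nodes(lab, np.ones(lab.shape, dtype=np.uint8))
        values = np.ones(lab.shape)
        values[4, 4, 4] = 2.35  # one cube voxel raised
        img = VoxelImage(values=values, affine=AFFINE2MM)
        profile = extract_profile(img, ns, "s1")
        assert profile.values[0] == pytest.approx((26 * 1.0 + 2.35) / 27)

    def test_noise_free_phantom_recovers_planted_values(self, small_atlas):
        config = SimulationConfig(n_subjects=3, noise_sd=0.0, seed=5)
        profiles, _ = simulate_profiles(small_atlas, config)
        ns = select_nodes(
            small_atlas.labels,
            binarize_gm(small_atlas.gm_prob),
            limbic_ids=small_atlas.limbic_ids,
        )
        for planted in profiles:
            img = render_image(planted, small_atlas, voxel_noise_sd=0.0)
            got = extract_profile(img, ns, planted.subject_id)
            np.testing.assert_allclose(got.values, planted.values, atol=1e-12)

    def test_non_finite_voxel_names_node(self):
        lab = _atlas_with_centers([(5, 5, 5)])
        ns = select_nodes(lab, np.ones(lab.shape, dtype=np.uint8))
        values = np.ones(lab.shape)
        values[5, 5, 5] = np.nan
        img = VoxelImage(values=values, affine=AFFINE2MM)
        with pytest.raises(ValueError, match="node 1"):
            extract_profile(img, ns, "s1")
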