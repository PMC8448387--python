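"""Segmentation, volume, skeleton topology, and soma-density counting."""

import numpy as np
import pytest

from calwave.morpho import (branch_metrics, cell_volume, count_density,
                            segment_cells, skeletonize_cell, soma_centroids)
from calwave.pipeline import analyze_morph_stack
from calwave.synthetic import (MorphGroupConfig, cylinder_phantom,
                               h_tree_phantom, random_tree_phantom,
                               simulate_morph_group,
                               simulate_morphology_stack, sphere_phantom,
                               y_tree_phantom)


class TestSegmentation:
    def test_blank_stack_gives_no_cells(self):
        labels, n = segment_cells(np.zeros((10, 10, 10)))
        assert n == 0 and not labels.any()

    def test_two_disjoint_phantoms_get_two_labels(self):
        stack = np.zeros((10, 30, 10))
        stack[3:7, 2:8, 3:7] = 1000.0
        stack[3:7, 20:26, 3:7] = 1000.0
        labels, n = segment_cells(stack, intensity_threshold=500)
        assert n == 2
        assert (labels[3:7, 2:8, 3:7] == 1).all()
        assert (labels[3:7, 20:26, 3:7] == 2).all()

    def test_touching_phantoms_merge(self):
        stack = np.zeros((10, 20, 10))
        stack[3:7, 2:10, 3:7] = 1000.0
        stack[3:7, 10:18, 3:7] = 1000.0      # shares a face
        _, n = segment_cells(stack, intensity_threshold=500)
        assert n == 1

    def test_min_voxels_filter(self):
        stack = np.zeros((10, 20, 10))
        stack[5, 2, 5] = 1000.0
        stack[3:7, 10:18, 3:7] = 1000.0
        _, n = segment_cells(stack, intensity_threshold=500, min_voxels=5)
        assert n == 1


class TestVolume:
    def test_cube_volume(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[1:11, 1:11, 1:11] = True
        assert cell_volume(mask, 1.0) == 1000.0

    def test_anisotropic_voxels(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        assert cell_volume(mask, (2.0, 1.0, 0.5)) == pytest.approx(8.0)

    def test_sphere_within_five_percent_of_analytic(self):
        spec = sphere_phantom(radius=6.57, voxel_size=0.5)
        stack, spec = simulate_morphology_stack(spec)
        df = analyze_morph_stack(stack, spec.voxel_size)
        assert len(df) == 1
        vol = df.volume_um3.iloc[0]
        assert abs(vol - spec.expected_volume) / spec.expected_volume < 0.05

    def test_volume_additivity_under_split(self):
        mask = np.zeros((6, 6, 12), dtype=bool)
        mask[1:5, 1:5, 1:11] = True
        total = cell_volume(mask, 1.0)
        left, right = mask.copy(), mask.copy()
        left[:, :, 6:] = False
        right[:, :, :6] = False
        assert cell_volume(left, 1.0) + cell_volume(right, 1.0) == total


class TestSkeleton:
    def _metrics(self, spec):
        stack, spec = simulate_morphology_stack(spec)
        df = analyze_morph_stack(stack, spec.voxel_size)
        assert len(df) == 1
        return df.iloc[0], spec

    def test_cylinder_is_one_unbranched_segment(self):
        row, spec = self._metrics(cylinder_phantom(length=30, radius=2,
                                                   voxel_size=1))
        assert row.n_branchpoints == 0
        assert row.n_branches == 1
        assert abs(row.total_branch_length_um - 30) / 30 <= 0.10

    def test_y_tree_has_one_branchpoint_three_branches(self):
        row, spec = self._metrics(y_tree_phantom(segment_length=20))
        assert row.n_branchpoints == 1
        assert row.n_branches == 3
        assert row.mean_branch_length_um == pytest.approx(20, rel=0.10)

    def test_h_tree_has_two_branchpoints(self):
        row, _ = self._metrics(h_tree_phantom())
        assert row.n_branchpoints == 2
        assert row.n_branches == 5

    def test_single_voxel_component_degenerates_to_point(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        skel = skeletonize_cell(mask, 1.0)
        bm = branch_metrics(skel)
        assert bm.n_branchpoints == 0 and bm.n_branches == 0
        assert bm.mean_branch_length == 0.0

    def test_random_trees_match_constructed_topology(self):
        for seed in (1, 2, 3, 4, 5):
            spec = random_tree_phantom(n_branches=5, seed=seed)
            stack, spec = simulate_morphology_stack(spec)
            df = analyze_morph_stack(stack, spec.voxel_size)
            assert len(df) == 1
            assert df.n_branches.iloc[0] == spec.expected_branches
            assert df.n_branchpoints.iloc[0] == spec.expected_branchpoints

    def test_pruning_never_increases_branch_count(self):
        spec = random_tree_phantom(n_branches=7, seed=9)
        stack, spec = simulate_morphology_stack(spec)
        from calwave.morpho import segment_cells
        labels, n = segment_cells(stack, intensity_threshold=500)
        mask = labels == 1
        counts = [branch_metrics(skeletonize_cell(mask, spec.voxel_size,
                                                  prune_length=p)).n_branches
                  for p in (0.0, 1.6, 3.2, 6.4)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestGroupRecovery:
    def test_group_means_recover_planted_values(self):
        """CTL-like phantoms: pipeline volume and branch length within
        2 SEM of the planted per-cell values."""
        cells = simulate_morph_group(MorphGroupConfig(), n_cells=10, seed=21)
        vols, planted_vols, lens, planted_lens = [], [], [], []
        for stack, spec in cells:
            df = analyze_morph_stack(stack, spec.voxel_size)
            assert len(df) == 1
            vols.append(df.volume_um3.iloc[0])
            planted_vols.append(spec.realized_volume)
            lens.append(df.mean_branch_length_um.iloc[0])
            planted_lens.append(np.mean(spec.expected_branch_lengths))
        n = len(vols)
        sem_v = np.std(vols, ddof=1) / np.sqrt(n)
        sem_l = np.std(lens, ddof=1) / np.sqrt(n)
        assert abs(np.mean(vols) - np.mean(planted_vols)) <= 2 * sem_v
        assert abs(np.mean(lens) - np.mean(planted_lens)) <= 2 * sem_l


class TestDensity:
    def test_empty_field(self):
        d = count_density(np.empty((0, 2)))
        assert d.count == 0

    def test_planted_somas_counted_exactly(self, rng):
        pts = np.column_stack([rng.uniform(0, 50, 18), rng.uniform(0, 200, 18)])
        assert count_density(pts).count == 18

    def test_max_edge_is_excluded(self):
        pts = np.array([[50.0, 100.0], [0.0, 200.0], [0.0, 0.0]])
        assert count_density(pts).count == 1     # only the origin corner

    def test_field_outside_image_rejected(self):
        with pytest.raises(ValueError):
            count_density(np.empty((0, 2)), field_origin=(10.0, 0.0),
                          image_extent=(50.0, 200.0))

    def test_centroids_from_labeled_image(self):
        img = np.zeros((20, 20), dtype=int)
        img[2:4, 2:4] = 1
        img[10:12, 14:16] = 2
        pts = soma_centroids(img, pixel_size=2.0)
        assert pts.shape == (2, 2)
        assert pts[0] == pytest.approx((5.0, 5.0))
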