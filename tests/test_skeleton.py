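"""Skeletonization, graph tracing, local thickness and the descriptor set."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from mitomorph import synth
from mitomorph.core import BinaryMask, ContractError
from mitomorph.skeleton import (DESCRIPTOR_COLUMNS, build_graph,
                                local_thickness, longest_shortest_path,
                                measure_mask, prune_spurs, skeletonize,
                                summarize_cell)
from conftest import (brute_force_graph_diameter, make_abstract_graph,
                      random_tree_graph)


def tube_mask(truth):
    return BinaryMask(truth.true_mask, truth.voxel_spacing)


class TestSkeletonize:
    def test_empty_mask_empty_skeleton(self):
        mask = BinaryMask(np.zeros((5, 5, 5), bool), (0.1,) * 3)
        assert not skeletonize(mask).any()

    def test_anisotropic_input_rejected(self):
        mask = BinaryMask(np.ones((5, 5, 5), bool), (0.9, 0.18, 0.18))
        with pytest.raises(ContractError):
            skeletonize(mask)

    def test_straight_cylinder_single_chain(self, straight_tube_truth):
        skel = skeletonize(tube_mask(straight_tube_truth))
        graph = build_graph(skel, 0.1)
        junctions = [n for n in graph.nodes if n.kind == "junction"]
        assert len(junctions) == 0
        assert graph.n_branches == 1

    def test_component_count_preserved(self):
        g = synth.generate_branch_graph(5, 3, length_range=(1.5, 2.5),
                                        radius_range=(0.2, 0.2),
                                        box=(6.4, 6.4, 6.4),
                                        attach_probability=0.0)
        truth = synth.rasterize_network(g, (0.1,) * 3)
        skel = skeletonize(tube_mask(truth))
        s = np.ones((3, 3, 3))
        _, n_mask = ndi.label(truth.true_mask, structure=s)
        _, n_skel = ndi.label(skel, structure=s)
        assert n_mask == n_skel == 3


class TestBuildGraph:
    def test_straight_chain_hand_counts(self):
        skel = np.zeros((3, 3, 12), bool)
        skel[1, 1, 1:11] = True  # 10 voxels, 9 steps
        graph = build_graph(skel, 0.1)
        assert graph.n_branches == 1
        br = graph.branches[0]
        assert br.path_length == pytest.approx(0.9)
        assert br.euclidean_distance == pytest.approx(0.9)

    def test_y_shape_topology_and_lengths(self, y_skeleton):
        skel, spacing, lengths = y_skeleton
        graph = build_graph(skel, spacing)
        kinds = [n.kind for n in graph.nodes]
        assert kinds.count("junction") == 1
        assert kinds.count("end") == 3
        assert graph.n_branches == 3
        np.testing.assert_allclose(sorted(graph.branch_lengths()),
                                   sorted(lengths), rtol=1e-12)

    def test_path_length_at_least_euclidean(self):
        g = synth.generate_branch_graph(13, 6)
        truth = synth.rasterize_network(g, (0.1,) * 3)
        skel = skeletonize(tube_mask(truth))
        graph = build_graph(skel, 0.1)
        for br in graph.branches:
            assert br.path_length >= br.euclidean_distance - 1e-9

    def test_isolated_voxel_degenerate_branch(self):
        skel = np.zeros((5, 5, 5), bool)
        skel[2, 2, 2] = True
        graph = build_graph(skel, 0.1)
        assert graph.n_branches == 1
        assert graph.branches[0].path_length == 0.0

    def test_pure_cycle_traced_as_loop(self):
        # diamond ring of 8 diagonal steps: every voxel has exactly 2 neighbours
        ring = [(2, 4), (3, 5), (4, 6), (5, 5), (6, 4), (5, 3), (4, 2), (3, 3)]
        skel = np.zeros((3, 9, 9), bool)
        for y, x in ring:
            skel[1, y, x] = True
        graph = build_graph(skel, 0.1)
        assert graph.n_branches == 1
        br = graph.branches[0]
        assert br.node_a == br.node_b
        assert br.path_length == pytest.approx(8 * np.sqrt(2) * 0.1)


class TestPruneSpurs:
    def test_short_spur_removed_long_arms_kept(self, y_skeleton):
        skel, spacing, lengths = y_skeleton
        skel[3, 40, 55] = skel[4, 40, 55] = True  # 2-voxel spur off the +x arm
        pruned = prune_spurs(skel, spacing, min_length=0.5)
        graph = build_graph(pruned, spacing)
        assert graph.n_branches == 3
        np.testing.assert_allclose(sorted(graph.branch_lengths()),
                                   sorted(lengths), rtol=1e-12)

    def test_no_change_when_all_branches_long(self, y_skeleton):
        skel, spacing, _ = y_skeleton
        np.testing.assert_array_equal(prune_spurs(skel, spacing, 0.5), skel)


class TestLocalThickness:
    def test_ball_center_thickness_is_diameter(self, ball_mask):
        mask, r = ball_mask
        thick = local_thickness(mask)
        c = tuple(s // 2 for s in mask.shape)
        assert thick[c] == pytest.approx(2 * r, abs=2 * mask.spacing[0])

    def test_cylinder_axis_thickness(self, straight_tube_truth):
        mask = tube_mask(straight_tube_truth)
        thick = local_thickness(mask)
        skel = skeletonize(mask)
        on_axis = thick[skel]
        assert np.median(on_axis) == pytest.approx(0.6, abs=0.15)

    def test_zero_outside_mask(self, ball_mask):
        mask, _ = ball_mask
        thick = local_thickness(mask)
        assert np.all(thick[~mask.data] == 0)

    def test_dilation_never_decreases_thickness(self, ball_mask):
        mask, _ = ball_mask
        before = local_thickness(mask)
        dilated = BinaryMask(ndi.binary_dilation(mask.data), mask.spacing)
        after = local_thickness(dilated)
        assert np.all(after[mask.data] >= before[mask.data] - 1e-9)


class TestLongestShortestPath:
    def test_single_branch_is_its_length(self):
        g = make_abstract_graph([(0, 1, 3.7)])
        assert longest_shortest_path(g) == pytest.approx(3.7)

    def test_y_hand_computed(self):
        g = make_abstract_graph([(0, 1, 2.0), (0, 2, 3.0), (0, 3, 4.0)])
        assert longest_shortest_path(g) == pytest.approx(7.0)

    def test_disconnected_components_take_max(self):
        g = make_abstract_graph([(0, 1, 2.0), (2, 3, 5.0)])
        assert longest_shortest_path(g) == pytest.approx(5.0)

    def test_empty_graph_zero_with_warning(self):
        g = make_abstract_graph([(0, 1, 1.0)])
        g.branches = []
        with pytest.warns(UserWarning):
            assert longest_shortest_path(g) == 0.0

    def test_random_trees_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            g = random_tree_graph(rng)
            assert longest_shortest_path(g) == pytest.approx(
                brute_force_graph_diameter(g))

    def test_parallel_edges_use_shorter(self):
        g = make_abstract_graph([(0, 1, 5.0), (0, 1, 2.0), (1, 2, 1.0)])
        assert longest_shortest_path(g) == pytest.approx(3.0)


class TestSummarize:
    def test_single_tube_descriptors(self, straight_tube_truth):
        mask = tube_mask(straight_tube_truth)
        m = measure_mask(mask)
        assert m.n_branches == 1
        assert m.avg_branch_length == m.max_branch_length
        assert m.avg_branch_length == pytest.approx(6.0, rel=0.12)
        assert m.sd_branch_thickness == 0.0
        assert m.avg_branch_thickness == pytest.approx(0.6, rel=0.15)
        assert m.branch_aspect_ratio == pytest.approx(6.0 / 0.6, rel=0.25)
        assert m.network_volume == pytest.approx(np.pi * 0.09 * 6, rel=0.10)

    def test_two_parallel_tubes_additivity(self):
        L, r = 4.0, 0.3
        p1 = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0 + L]])
        p2 = np.array([[1.0, 2.6, 1.0], [1.0, 2.6, 1.0 + L]])
        g1 = synth.TruthGraph(p1, [synth.Branch(0, 1, p1, r)], (3.6, 3.6, 6.0), 0)
        g2 = synth.TruthGraph(np.vstack([p1, p2]),
                              [synth.Branch(0, 1, p1, r), synth.Branch(2, 3, p2, r)],
                              (3.6, 3.6, 6.0), 0)
        m1 = measure_mask(tube_mask(synth.rasterize_network(g1, (0.1,) * 3)))
        m2 = measure_mask(tube_mask(synth.rasterize_network(g2, (0.1,) * 3)))
        assert m2.network_volume == pytest.approx(2 * m1.network_volume, rel=0.01)
        assert m2.avg_branch_length == pytest.approx(m1.avg_branch_length, rel=0.02)
        assert m2.avg_branch_thickness == pytest.approx(m1.avg_branch_thickness,
                                                        rel=0.02)

    def test_empty_graph_flagged_degenerate(self):
        mask = BinaryMask(np.zeros((5, 5, 5), bool), (0.1,) * 3)
        m = measure_mask(mask)
        assert m.degenerate
        assert m.descriptor_vector().tolist() == [0.0] * len(DESCRIPTOR_COLUMNS)

    def test_rotation_invariance_90deg(self):
        g = synth.generate_branch_graph(21, 4, box=(6.4, 6.4, 6.4))
        truth = synth.rasterize_network(g, (0.1,) * 3)
        mask = tube_mask(truth)
        rot = BinaryMask(np.rot90(truth.true_mask, k=1, axes=(1, 2)).copy(),
                         truth.voxel_spacing)
        a = measure_mask(mask).descriptor_vector()
        b = measure_mask(rot).descriptor_vector()
        np.testing.assert_allclose(a, b, rtol=0.05, atol=0.02)

    def test_thickness_recovery_monotone_across_radii(self):
        means = []
        for r in (0.2, 0.3, 0.5):
            pts = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 5.0]])
            g = synth.TruthGraph(pts, [synth.Branch(0, 1, pts, r)],
                                 (2.2, 2.2, 6.0), 0)
            truth = synth.rasterize_network(g, (0.1,) * 3)
            means.append(measure_mask(tube_mask(truth)).avg_branch_thickness)
        assert means[0] < means[1] < means[2]
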