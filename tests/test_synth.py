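"""Generator correctness: the answer key must itself be right."""

import numpy as np
import pytest

from mitomorph import synth
from mitomorph.core import ParameterError


class TestBranchGraph:
    def test_empty_graph(self):
        g = synth.generate_branch_graph(0, 0)
        assert g.n_branches == 0 and len(g.nodes) == 0

    def test_single_branch_length_in_range(self):
        g = synth.generate_branch_graph(5, 1, length_range=(2.0, 3.0))
        assert g.n_branches == 1
        assert len(g.nodes) == 2
        assert 2.0 <= g.branches[0].length <= 3.0

    def test_seed_determinism_byte_identical(self):
        a = synth.generate_branch_graph(7, 6).to_json()
        b = synth.generate_branch_graph(7, 6).to_json()
        assert a == b

    def test_different_seeds_differ(self):
        assert synth.generate_branch_graph(1, 4).to_json() \
            != synth.generate_branch_graph(2, 4).to_json()

    def test_json_round_trip(self):
        g = synth.generate_branch_graph(3, 5)
        g2 = synth.TruthGraph.from_json(g.to_json())
        assert g2.to_json() == g.to_json()

    def test_geometry_invariants(self):
        g = synth.generate_branch_graph(11, 10, attach_probability=0.5)
        box = np.asarray(g.box)
        for br in g.branches:
            assert br.radius > 0
            assert np.all(br.points >= 0) and np.all(br.points <= box)
            assert {br.node_a, br.node_b} <= set(range(len(g.nodes)))

    def test_disjoint_mode_separates_tubes(self):
        g = synth.generate_branch_graph(2, 4, radius_range=(0.2, 0.2),
                                        attach_probability=0.0)
        # every branch has its own pair of nodes
        used = [n for br in g.branches for n in (br.node_a, br.node_b)]
        assert len(set(used)) == 2 * g.n_branches

    @pytest.mark.parametrize("kwargs", [
        {"n_branches": -1},
        {"n_branches": 1, "length_range": (3.0, 2.0)},
        {"n_branches": 1, "radius_range": (0.0, 0.2)},
        {"n_branches": 1, "box": (0.0, 5.0, 5.0)},
    ])
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ParameterError):
            synth.generate_branch_graph(0, **{"length_range": (2.0, 4.0),
                                              "radius_range": (0.2, 0.3),
                                              "box": (6.4, 6.4, 6.4), **kwargs})


class TestRasterize:
    def test_cylinder_volume_within_10pct(self, straight_tube_truth):
        truth = straight_tube_truth
        analytic = np.pi * 0.3 ** 2 * 6.0
        assert truth.true_network_volume == pytest.approx(analytic, rel=0.10)

    def test_network_volume_is_voxel_count(self, straight_tube_truth):
        t = straight_tube_truth
        assert t.true_network_volume == pytest.approx(
            t.true_mask.sum() * np.prod(t.voxel_spacing))

    def test_empty_graph_all_zero_mask(self):
        g = synth.generate_branch_graph(0, 0, box=(2.0, 2.0, 2.0))
        t = synth.rasterize_network(g, (0.1, 0.1, 0.1))
        assert not t.true_mask.any()

    def test_refinement_converges_to_analytic(self):
        # radius incommensurate with the grid avoids boundary-lattice flukes
        L, r = 6.0, 0.313
        pts = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0 + L]])
        g = synth.TruthGraph(pts, [synth.Branch(0, 1, pts, r)],
                             box=(2.0, 2.0, L + 2.0), seed=0)
        capsule = np.pi * r ** 2 * L + 4 / 3 * np.pi * r ** 3
        errs = []
        for sp in (0.1, 0.05, 0.025):
            t = synth.rasterize_network(g, (sp, sp, sp))
            errs.append(abs(t.true_network_volume - capsule) / capsule)
        assert errs[2] < errs[1] < errs[0]


class TestRender:
    def test_identity_imaging_proportional_to_mask(self, straight_tube_truth):
        model = synth.ImagingModel(psf_sigma=(0, 0, 0), photon_scale=10.0,
                                   read_noise_sigma=0.0,
                                   background=(0, 0, 0, 0), shot_noise=False)
        img = synth.render_image(straight_tube_truth, model, seed=0)
        np.testing.assert_allclose(img.data,
                                   10.0 * straight_tube_truth.true_mask)

    def test_constant_background_on_empty_mask(self):
        g = synth.generate_branch_graph(0, 0, box=(2.0, 2.0, 2.0))
        t = synth.rasterize_network(g, (0.1, 0.1, 0.1))
        model = synth.ImagingModel(photon_scale=0.0, read_noise_sigma=0.0,
                                   background=(7.0, 0, 0, 0))
        img = synth.render_image(t, model, seed=1)
        # Poisson(7) per voxel: mean over the stack ≈ 7
        assert img.data.mean() == pytest.approx(7.0, rel=0.05)

    def test_render_reproducible_under_seed(self, straight_tube_truth):
        m = synth.ImagingModel()
        a = synth.render_image(straight_tube_truth, m, seed=3)
        b = synth.render_image(straight_tube_truth, m, seed=3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_monte_carlo_mean_matches_expectation(self):
        # small grid, many draws: sample mean within 3 SEs of the noiseless image
        L, r = 1.0, 0.2
        pts = np.array([[0.5, 0.5, 0.2], [0.5, 0.5, 0.2 + L]])
        g = synth.TruthGraph(pts, [synth.Branch(0, 1, pts, r)],
                             box=(1.0, 1.0, 1.6), seed=0)
        t = synth.rasterize_network(g, (0.2, 0.2, 0.2))
        model = synth.ImagingModel(photon_scale=20.0, read_noise_sigma=1.0,
                                   background=(3.0, 0, 0, 0))
        noiseless = synth.render_image(
            t, synth.ImagingModel(photon_scale=20.0, read_noise_sigma=0.0,
                                  background=(3.0, 0, 0, 0), shot_noise=False),
            seed=0).data
        n = 100
        stack = np.stack([synth.render_image(t, model, seed=s).data
                          for s in range(n)])
        mean = stack.mean(axis=0)
        se = stack.std(axis=0, ddof=1) / np.sqrt(n)
        frac_out = np.mean(np.abs(mean - noiseless) > 3 * np.maximum(se, 1e-9))
        assert frac_out < 0.02  # clamping at 0 makes a strict bound unfair


class TestPhantoms:
    def test_sphere_closed_form(self):
        t = synth.generate_cell_phantom("sphere", {"radius": 4.0}, (0.18,) * 3)
        assert t.true_cell_volume == pytest.approx(4 / 3 * np.pi * 64.0)
        assert t.true_network_volume == pytest.approx(t.true_cell_volume, rel=0.05)

    def test_ellipsoid_equals_sphere_when_axes_equal(self):
        s = synth.generate_cell_phantom("sphere", {"radius": 3.0}, (0.2,) * 3)
        e = synth.generate_cell_phantom("ellipsoid",
                                        {"semi_axes": (3.0, 3.0, 3.0)}, (0.2,) * 3)
        assert e.true_cell_volume == pytest.approx(s.true_cell_volume)

    def test_stacked_profile_prism(self):
        t = synth.generate_cell_phantom(
            "stacked-profile", {"areas": [10.0] * 5, "slab_height": 0.9},
            (0.18,) * 3)
        assert t.true_cell_volume == pytest.approx(45.0)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ParameterError):
            synth.generate_cell_phantom("ellipsoid",
                                        {"semi_axes": (0.0, 1.0, 1.0)}, (0.1,) * 3)


class TestMosaic:
    def test_single_constant_area_polygon(self):
        t = synth.generate_apical_mosaic(0, 1, {"dist": "constant", "value": 25.0})
        assert t.true_polygon_areas[0] == pytest.approx(25.0)

    def test_seed_determinism(self):
        a = synth.generate_apical_mosaic(4, 9)
        b = synth.generate_apical_mosaic(4, 9)
        for pa, pb in zip(a.polygons, b.polygons):
            np.testing.assert_array_equal(pa, pb)

    def test_total_area_below_field_area(self):
        t = synth.generate_apical_mosaic(1, 25, field=(50.0, 50.0))
        assert t.true_polygon_areas.sum() <= 2500.0

    def test_polygons_disjoint(self):
        from shapely.geometry import Polygon
        t = synth.generate_apical_mosaic(2, 16)
        polys = [Polygon([(x, y) for y, x in p]) for p in t.polygons]
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                assert not polys[i].intersects(polys[j])

    def test_true_areas_match_shoelace(self):
        from mitomorph.metrics import shoelace_area
        t = synth.generate_apical_mosaic(3, 8)
        for poly, area in zip(t.polygons, t.true_polygon_areas):
            assert shoelace_area(poly) == pytest.approx(area)
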