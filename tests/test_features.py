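"""Feature-formula unit tests: counts, thickness, volume, tortuosity,
angles, growth extension, coverage, cube-law residuals and disc shape."""

import numpy as np
import pytest

from pcsvn.features import (
    ARTERIAL_FEATURES,
    SHAPE_FEATURES,
    branch_angles,
    count_features,
    extract_all,
    growth_extension,
    murray_l1_fit_error,
    shape_features,
    thickness_stats,
    tortuosity_stats,
    total_volume,
    vessel_to_disc_percent,
)
from pcsvn.skeleton import SkeletonGraph, SkeletonNode, VesselMask, VesselSegment


def make_graph(nodes, segments, root=0, scale=35.0):
    """nodes: list of (id, rc, kind, gen); segments: list of dicts."""
    g = SkeletonGraph(scale)
    for nid, rc, kind, gen in nodes:
        g.nodes[nid] = SkeletonNode(nid, rc, kind, gen)
    for i, s in enumerate(segments):
        g.segments[i] = VesselSegment(**s)
    g.root_id = root
    return g


def seg(parent, child, path, arc, chord, thick=0.1):
    return dict(
        pixel_path=np.array(path),
        arc_length_cm=arc,
        chord_cm=chord,
        thickness_cm=thick,
        parent_node=parent,
        child_node=child,
    )


def make_segments(values):
    """Bare segments carrying (arc, chord, thickness)."""
    return [
        VesselSegment(
            pixel_path=np.array([[0, 0], [0, 1]]),
            arc_length_cm=a,
            chord_cm=c,
            thickness_cm=t,
            parent_node=0,
            child_node=1,
        )
        for a, c, t in values
    ]


class TestCounts:
    def test_y_tree_counts(self):
        # root end -> branch -> two leaves
        g = make_graph(
            [(0, (10, 0), "end", 0), (1, (10, 5), "branch", 1), (2, (5, 9), "end", 2), (3, (15, 9), "end", 2)],
            [
                seg(0, 1, [[10, 0], [10, 5]], 5 / 35, 5 / 35),
                seg(1, 2, [[10, 5], [5, 9]], 6 / 35, 6 / 35),
                seg(1, 3, [[10, 5], [15, 9]], 6 / 35, 6 / 35),
            ],
        )
        c = count_features(g)
        assert (c.num_end_points, c.num_branch_points) == (3, 1)
        assert c.murray_branches_used == 0
        assert c.total_branches == 3 == c.num_end_points + c.num_branch_points - 1

    def test_single_segment_counts(self):
        g = make_graph(
            [(0, (0, 0), "end", 0), (1, (0, 9), "end", 1)],
            [seg(0, 1, [[0, 0], [0, 9]], 9 / 35, 9 / 35)],
        )
        c = count_features(g)
        assert (c.num_end_points, c.num_branch_points, c.murray_branches_used) == (2, 0, 0)

    def test_full_binary_tree_depth3_rooted_at_end_node(self):
        # root end node feeds a full binary tree with 7 internal nodes and 8
        # leaves; exhaustive count on the fixture: node 1 is the first branch
        # (child of the root), binary expansion two levels further, leaves at
        # edge-depth 4
        nodes = [(0, (0, 0), "end", 0), (1, (0, 10), "branch", 1)]
        segments = [seg(0, 1, [[0, 0], [0, 10]], 10 / 35, 10 / 35)]
        nid = 2
        frontier = [1]
        for depth in (2, 3):
            nxt = []
            for parent in frontier:
                for _ in range(2):
                    nodes.append((nid, (nid, nid), "branch", depth))
                    segments.append(seg(parent, nid, [[0, 0], [3, 4]], 5 / 35, 5 / 35))
                    nxt.append(nid)
                    nid += 1
            frontier = nxt
        for parent in frontier:
            for _ in range(2):
                nodes.append((nid, (nid, nid), "end", 4))
                segments.append(seg(parent, nid, [[0, 0], [3, 4]], 5 / 35, 5 / 35))
                nid += 1
        g = make_graph(nodes, segments)
        c = count_features(g)
        assert c.num_end_points == 9
        assert c.num_branch_points == 7
        assert c.murray_branches_used == 6
        assert c.num_generations == 3  # deepest branching generation
        assert c.total_branches == 15 == c.num_end_points + c.num_branch_points - 1

    def test_empty_graph_all_zero(self):
        g = SkeletonGraph(35.0)
        c = count_features(g)
        assert (c.num_end_points, c.num_branch_points, c.murray_branches_used, c.total_branches, c.num_generations) == (0, 0, 0, 0, 0)


class TestThicknessAndVolume:
    def test_two_point_population_sd(self):
        mean, sd = thickness_stats(make_segments([(1, 1, 0.1), (1, 1, 0.3)]))
        assert mean == pytest.approx(0.2)
        assert sd == pytest.approx(0.1)

    def test_single_segment_sd_zero(self):
        mean, sd = thickness_stats(make_segments([(1, 1, 0.17)]))
        assert sd == 0.0

    def test_formula_oracle_on_random_segments(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(0.05, 0.3, size=5)
        segs = make_segments([(1, 1, ti) for ti in t])
        mean, sd = thickness_stats(segs)
        assert mean == pytest.approx(t.sum() / 5)
        assert sd == pytest.approx(np.sqrt(((t - t.mean()) ** 2).sum() / 5))

    def test_no_segments_gives_sentinel(self):
        mean, sd = thickness_stats([])
        assert np.isnan(mean) and np.isnan(sd)

    def test_cylinder_volume(self):
        vol = total_volume(make_segments([(3.0, 3.0, 0.2)]))
        assert vol == pytest.approx(np.pi * 0.01 * 3.0)

    def test_zero_segments_zero_volume(self):
        assert total_volume([]) == 0.0

    def test_volume_is_sum_of_per_segment_cylinders(self):
        vals = [(2.0, 1.9, 0.1), (1.0, 0.9, 0.25), (4.0, 3.5, 0.07)]
        vol = total_volume(make_segments(vals))
        oracle = sum(np.pi * (t / 2) ** 2 * a for a, _, t in vals)
        assert vol == pytest.approx(oracle)


class TestTortuosity:
    def test_straight_segment_ratio_one(self):
        m, sd, mx, _ = tortuosity_stats(make_segments([(2.0, 2.0, 0.1)]))
        assert m == pytest.approx(1.0)
        assert mx == pytest.approx(1.0)

    def test_semicircle_ratio_pi_over_two(self):
        r = 1.0
        arc, chord = np.pi * r, 2 * r
        m, *_ = tortuosity_stats(make_segments([(arc, chord, 0.1)]))
        assert m == pytest.approx(np.pi / 2, rel=1e-12)

    def test_mixed_set_matches_formula_oracle(self):
        m, sd, mx, _ = tortuosity_stats(
            make_segments([(1.0, 1.0, 0.1), (1.2, 1.0, 0.1), (1.4, 1.0, 0.1)])
        )
        assert m == pytest.approx(1.2)
        assert mx == pytest.approx(1.4)
        assert sd == pytest.approx(np.sqrt(0.08 / 3))

    def test_zero_chord_segment_excluded(self):
        m, *_ = tortuosity_stats(make_segments([(1.0, 0.0, 0.1), (1.5, 1.0, 0.1)]))
        assert m == pytest.approx(1.5)

    def test_all_ratios_at_least_one_on_extracted_tree(self, clean_tree):
        from pcsvn.features import extract_graph

        _, mask = clean_tree
        g = extract_graph(mask)
        for s in g.segments.values():
            if s.chord_cm > 0:
                assert s.arc_length_cm / s.chord_cm >= 1.0 - 1e-9


class TestBranchAngles:
    def _bifurcation(self, child1_path, child2_path):
        nodes = [
            (0, (20, 0), "end", 0),
            (1, (20, 20), "branch", 1),
            (2, tuple(child1_path[-1]), "end", 2),
            (3, tuple(child2_path[-1]), "end", 2),
        ]
        segments = [
            seg(0, 1, [[20, c] for c in range(0, 21)], 20 / 35, 20 / 35),
            seg(1, 2, child1_path, 0.2, 0.2),
            seg(1, 3, child2_path, 0.2, 0.2),
        ]
        return make_graph(nodes, segments)

    def test_orthogonal_children_measure_90_degrees(self):
        p1 = [[20, 20], [20, 21], [20, 22], [20, 23], [20, 24], [20, 25]]
        p2 = [[20, 20], [21, 20], [22, 20], [23, 20], [24, 20], [25, 20]]
        g = self._bifurcation(p1, p2)
        _, mean, _ = branch_angles(g)
        assert mean == pytest.approx(90.0)

    def test_colinear_opposite_children_measure_180_degrees(self):
        p1 = [[20, 20], [20, 21], [20, 22], [20, 23], [20, 24]]
        p2 = [[20, 20], [20, 19], [20, 18], [20, 17], [20, 16]]
        g = self._bifurcation(p1, p2)
        _, mean, _ = branch_angles(g)
        assert mean == pytest.approx(180.0)

    def test_axis_and_diagonal_children_measure_45_degrees(self):
        p1 = [[20, 20], [20, 21], [20, 22], [20, 23], [20, 24], [20, 25]]
        p2 = [[20, 20], [21, 21], [22, 22], [23, 23], [24, 24], [25, 25]]
        g = self._bifurcation(p1, p2)
        _, mean, _ = branch_angles(g)
        assert mean == pytest.approx(45.0, abs=1.0)

    def test_short_branch_uses_last_pixel(self):
        p1 = [[20, 20], [20, 21], [20, 22], [20, 23], [20, 24], [20, 25]]
        p2 = [[20, 20], [21, 20], [22, 20]]  # only 2 px after the node
        g = self._bifurcation(p1, p2)
        _, mean, _ = branch_angles(g)
        assert mean == pytest.approx(90.0)

    def test_no_bifurcation_gives_sentinel(self):
        g = make_graph(
            [(0, (0, 0), "end", 0), (1, (0, 9), "end", 1)],
            [seg(0, 1, [[0, 0], [0, 9]], 9 / 35, 9 / 35)],
        )
        angles, mean, med = branch_angles(g)
        assert angles == [] and np.isnan(mean) and np.isnan(med)


class TestGrowthExtension:
    def _one_end_graph(self, rc):
        return make_graph(
            [(0, rc, "end", 0), (1, (rc[0], rc[1] + 5), "branch", 1)],
            [seg(0, 1, [list(rc), [rc[0], rc[1] + 5]], 5 / 35, 5 / 35)],
        )

    def test_center_of_disc_measures_radius(self):
        r_px = 105  # 3 cm at 35 px/cm
        yy, xx = np.mgrid[0:240, 0:240]
        disc = (yy - 120) ** 2 + (xx - 120) ** 2 <= r_px**2
        g = self._one_end_graph((120, 120))
        d = growth_extension(g, disc)
        assert d == pytest.approx(3.0, abs=0.05)

    def test_end_point_on_boundary_measures_zero(self):
        yy, xx = np.mgrid[0:240, 0:240]
        disc = (yy - 120) ** 2 + (xx - 120) ** 2 <= 105**2
        g = self._one_end_graph((120, 225))
        d = growth_extension(g, disc)
        assert d == pytest.approx(0.0, abs=0.05)

    def test_polygon_boundary_matches_brute_force_over_vertices(self):
        rng = np.random.default_rng(0)
        poly = rng.uniform(0, 200, size=(50, 2))
        nodes = [(i, (int(p[0]), int(p[1])), "end", 0) for i, p in enumerate([(10, 10), (100, 50), (180, 120)])]
        nodes.append((3, (50, 50), "branch", 1))
        segments = [seg(i, 3, [[nodes[i][1][0], nodes[i][1][1]], [50, 50]], 1, 1) for i in range(3)]
        g = make_graph(nodes, segments)
        d = growth_extension(g, poly)
        oracle = np.mean(
            [min(np.hypot(*(np.array(n[1], float) - v)) for v in poly) for n in nodes[:3]]
        ) / 35.0
        assert d == pytest.approx(oracle, rel=1e-9)


class TestCoverageAndMurray:
    def test_vessel_equal_disc_is_100_percent(self):
        disc = np.ones((10, 10), dtype=bool)
        assert vessel_to_disc_percent(disc, disc) == pytest.approx(100.0)

    def test_empty_vessel_is_zero_percent(self):
        disc = np.ones((10, 10), dtype=bool)
        assert vessel_to_disc_percent(np.zeros_like(disc), disc) == 0.0

    def test_empty_disc_raises(self):
        with pytest.raises(ValueError):
            vessel_to_disc_percent(np.ones((5, 5), bool), np.zeros((5, 5), bool))

    def test_known_stroke_area_matches_pixel_count_oracle(self):
        yy, xx = np.mgrid[0:100, 0:100]
        disc = (yy - 50) ** 2 + (xx - 50) ** 2 <= 45**2
        vessel = np.zeros_like(disc)
        vessel[48:53, 10:90] = True
        pct = vessel_to_disc_percent(vessel, disc)
        assert pct == pytest.approx(100.0 * (vessel & disc).sum() / disc.sum())

    def _murray_graph(self, tp, t1, t2):
        nodes = [
            (0, (0, 0), "end", 0),
            (1, (0, 10), "branch", 1),
            (2, (5, 15), "end", 2),
            (3, (-5, 15), "end", 2),
        ]
        segments = [
            seg(0, 1, [[0, 0], [0, 10]], 10 / 35, 10 / 35, thick=tp),
            seg(1, 2, [[0, 10], [5, 15]], 0.2, 0.2, thick=t1),
            seg(1, 3, [[0, 10], [5, 15]], 0.2, 0.2, thick=t2),
        ]
        return make_graph(nodes, segments)

    def test_perfect_murray_bifurcation_has_zero_residual(self):
        tp = 0.2
        tc = tp * 2 ** (-1 / 3)
        g = self._murray_graph(tp, tc, tc)
        assert murray_l1_fit_error(g) == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic_example(self):
        g = self._murray_graph(1.0, 0.9, 0.6)
        assert murray_l1_fit_error(g) == pytest.approx(0.055, abs=1e-12)

    def test_random_tree_matches_per_bifurcation_oracle(self, clean_tree):
        from pcsvn.features import extract_graph

        _, mask = clean_tree
        g = extract_graph(mask)
        res = []
        for nd in g.branch_nodes():
            kids = g.children_of(nd.id)
            par = g.parent_segment(nd.id)
            if par is None or len(kids) != 2:
                continue
            tp, t1, t2 = par.thickness_cm, kids[0].thickness_cm, kids[1].thickness_cm
            res.append(abs(tp**3 - t1**3 - t2**3) / tp**3)
        assert murray_l1_fit_error(g) == pytest.approx(np.mean(res))

    def test_no_bifurcations_gives_zero(self):
        g = make_graph(
            [(0, (0, 0), "end", 0), (1, (0, 9), "end", 1)],
            [seg(0, 1, [[0, 0], [0, 9]], 9 / 35, 9 / 35)],
        )
        assert murray_l1_fit_error(g) == 0.0


class TestShapeFeatures:
    def test_disc_area_and_circularity(self):
        scale = 35.0
        r_cm = 10.0
        size = int(2 * r_cm * scale) + 40
        yy, xx = np.mgrid[0:size, 0:size]
        c = size // 2
        disc = (yy - c) ** 2 + (xx - c) ** 2 <= (r_cm * scale) ** 2
        f = shape_features(disc, (c, c), scale)
        assert f["DiscArea"] == pytest.approx(np.pi * r_cm**2, rel=0.01)
        assert f["DiscCircularity"] == pytest.approx(1.0, abs=0.02)
        assert f["DiscEquivalentDiameter"] == pytest.approx(2 * r_cm, rel=0.01)
        assert f["CentroidToCordDisplacement"] == pytest.approx(0.0, abs=0.05)
        assert f["DiscMaxRadius"] == pytest.approx(r_cm, rel=0.02)
        assert f["DiscMinRadius"] == pytest.approx(r_cm, rel=0.02)

    def test_ellipse_eccentricity_matches_closed_form(self):
        a_cm, b_cm = 10.0, 6.0
        scale = 20.0
        size = 500
        yy, xx = np.mgrid[0:size, 0:size]
        c = size // 2
        disc = ((yy - c) / (b_cm * scale)) ** 2 + ((xx - c) / (a_cm * scale)) ** 2 <= 1.0
        f = shape_features(disc, (c, c), scale)
        ecc = np.sqrt(1 - (b_cm / a_cm) ** 2)
        assert f["DiscEccentricity"] == pytest.approx(ecc, abs=0.01)


class TestExtractAll:
    def test_vector_has_28_arterial_and_8_shape_features(self, clean_tree):
        _, mask = clean_tree
        fv = extract_all(mask)
        assert len(ARTERIAL_FEATURES) == 28
        assert len(SHAPE_FEATURES) == 8
        assert len(fv) == 36
        assert set(fv.arterial) == set(ARTERIAL_FEATURES)
        assert set(fv.shape) == set(SHAPE_FEATURES)

    def test_degenerate_single_vessel_counts_and_angle_sentinel(self):
        from pcsvn.synthetic import TreeSpec, rasterize, sample_tree

        spec = TreeSpec(mean_branch_points=0, sd_branch_points=0, seed=3)
        truth = sample_tree(spec)
        vessel, disc, cord = rasterize(truth)
        mask = VesselMask(grid=vessel, scale_px_per_cm=35.0, cord_xy=cord, boundary=disc)
        fv = extract_all(mask)
        assert fv.values["NumEndPoints"] == 2
        assert fv.values["NumBranchPoints"] == 0
        assert fv.values["MurrayBranchesUsed"] == 0
        assert np.isnan(fv.values["MeanAngle"])

    def test_overlapping_fields_agree_with_per_op_values(self, clean_tree):
        from pcsvn.features import extract_graph

        _, mask = clean_tree
        fv = extract_all(mask)
        g = extract_graph(mask)
        segs = list(g.segments.values())
        c = count_features(g)
        assert fv.values["NumBranchPoints"] == c.num_branch_points
        assert fv.values["NumEndPoints"] == c.num_end_points
        mt, st = thickness_stats(segs)
        assert fv.values["MeanThickness"] == pytest.approx(mt)
        assert fv.values["StdThickness"] == pytest.approx(st)
        assert fv.values["Volume"] == pytest.approx(total_volume(segs))
        _, ma, _ = branch_angles(g)
        assert fv.values["MeanAngle"] == pytest.approx(ma)

    def test_percent_fields_in_range_and_tortuosity_at_least_one(self, clean_tree):
        _, mask = clean_tree
        fv = extract_all(mask)
        assert 0 <= fv.values["VesselToDiscPercent"] <= 100
        assert fv.values["MeanTortuosity"] >= 1.0
        assert fv.values["MinTortuosity"] >= 1.0 - 1e-9
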