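"""Skeletonization and graph-extraction unit tests on hand-built rasters."""

import numpy as np
import pytest

from pcsvn.skeleton import (
    VesselMask,
    build_graph,
    measure_thickness,
    prune_spurs,
    skeletonize,
)
from tests.conftest import draw_bar, draw_plus


def neighbor_count(skel):
    from scipy.ndimage import convolve

    k = np.ones((3, 3), dtype=np.uint8)
    k[1, 1] = 0
    return convolve(skel.astype(np.uint8), k, mode="constant") * skel


class TestSkeletonize:
    def test_bar_thins_to_single_line_spanning_columns(self):
        grid = draw_bar(width=3)
        skel = skeletonize(grid)
        assert skel.sum() > 0
        assert (skel & ~grid).sum() == 0  # subset of foreground
        cols = np.where(skel.any(axis=0))[0]
        # spans the same columns up to end effects
        assert cols.min() <= 7 and cols.max() >= 52
        # 1-px wide: no 2x2 block fully set
        two_by_two = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        assert not two_by_two.any()

    def test_empty_mask_gives_empty_skeleton(self):
        skel = skeletonize(np.zeros((10, 10), dtype=bool))
        assert skel.sum() == 0

    def test_wide_y_shape_has_one_junction_cluster_and_three_tips(self):
        # rasterized Y with 5-px strokes; oracle = neighbor counting on the
        # thinned output
        grid = np.zeros((80, 80), dtype=bool)
        yy, xx = np.mgrid[0:80, 0:80]
        for (r0, c0), (r1, c1) in [((70, 40), (40, 40)), ((40, 40), (12, 15)), ((40, 40), (12, 65))]:
            # stamp a 5-px band along each arm
            n = 200
            rr = np.linspace(r0, r1, n)
            cc = np.linspace(c0, c1, n)
            for r, c in zip(rr, cc):
                grid |= (yy - r) ** 2 + (xx - c) ** 2 <= 2.5**2
        skel = skeletonize(grid)
        counts = neighbor_count(skel)
        tips = int(((counts == 1) & skel).sum())
        graph = build_graph(skel, cord_xy=(70, 40), scale=35.0)
        assert tips == 3
        assert len(graph.branch_nodes()) == 1
        assert len(graph.end_nodes()) == 3


class TestBuildGraph:
    def test_plus_sign_gives_one_branch_four_ends_four_segments(self):
        skel = draw_plus()
        g = build_graph(skel, cord_xy=(10, 10), scale=35.0)
        assert len(g.branch_nodes()) == 1
        assert len(g.end_nodes()) == 4
        assert len(g.segments) == 4

    def test_straight_line_two_ends_one_segment_arc_equals_chord(self):
        skel = np.zeros((20, 20), dtype=bool)
        skel[10, 5:15] = True
        g = build_graph(skel, cord_xy=(10, 5), scale=35.0)
        assert len(g.end_nodes()) == 2
        assert len(g.branch_nodes()) == 0
        assert len(g.segments) == 1
        seg = next(iter(g.segments.values()))
        assert seg.arc_length_cm == pytest.approx(seg.chord_cm)

    def test_diagonal_line_arc_length_uses_sqrt2_steps(self):
        skel = np.zeros((20, 20), dtype=bool)
        for i in range(10):
            skel[i + 3, i + 3] = True
        g = build_graph(skel, cord_xy=(3, 3), scale=35.0)
        seg = next(iter(g.segments.values()))
        assert seg.arc_length_cm == pytest.approx(9 * np.sqrt(2) / 35.0, rel=1e-9)

    def test_root_is_node_nearest_cord_and_generations_count_up(self):
        skel = draw_plus()
        g = build_graph(skel, cord_xy=(0, 10), scale=35.0)
        root = g.nodes[g.root_id]
        assert root.kind == "end"
        assert root.generation == 0
        assert {nd.generation for nd in g.nodes.values()} == {0, 1, 2}

    def test_disconnected_component_is_discarded_and_logged(self):
        skel = np.zeros((30, 30), dtype=bool)
        skel[5, 2:12] = True
        skel[25, 15:28] = True  # far from the cord
        g = build_graph(skel, cord_xy=(5, 2), scale=35.0)
        assert len(g.segments) == 1
        assert any("discarded" in line for line in g.repair_log)

    def test_segments_count_is_node_count_minus_one(self, clean_tree):
        from pcsvn.features import extract_graph

        _, mask = clean_tree
        g = extract_graph(mask)
        assert len(g.segments) == g.n - 1

    def test_arc_at_least_chord_for_every_segment(self, clean_tree):
        from pcsvn.features import extract_graph

        _, mask = clean_tree
        g = extract_graph(mask)
        for seg in g.segments.values():
            assert seg.arc_length_cm >= seg.chord_cm - 1e-12


class TestMeasureThickness:
    def test_constant_width_bar_measures_width_over_scale(self):
        grid = draw_bar(width=7)
        skel = skeletonize(grid)
        g = build_graph(skel, cord_xy=(21, 5), scale=35.0)
        measure_thickness(grid, g)
        seg = next(iter(g.segments.values()))
        assert seg.thickness_cm == pytest.approx(7 / 35.0, rel=0.05)

    def test_two_bars_give_two_distinct_thicknesses(self):
        grid = np.zeros((60, 60), dtype=bool)
        grid[10:13, 5:55] = True  # 3 px
        grid[40:49, 5:55] = True  # 9 px
        skel = skeletonize(grid)
        g = build_graph(skel, cord_xy=(11, 5), scale=35.0)
        # two components; keep both by measuring per component
        g1 = build_graph(skeletonize(grid[:30]), cord_xy=(11, 5), scale=35.0)
        measure_thickness(grid[:30], g1)
        g2 = build_graph(skeletonize(grid[30:]), cord_xy=(14, 5), scale=35.0)
        measure_thickness(grid[30:], g2)
        t1 = next(iter(g1.segments.values())).thickness_cm
        t2 = next(iter(g2.segments.values())).thickness_cm
        assert t1 == pytest.approx(3 / 35.0, rel=0.1)
        assert t2 == pytest.approx(9 / 35.0, rel=0.1)

    def test_tapering_wedge_matches_per_pixel_distance_oracle(self):
        # triangle-ish wedge: width grows linearly along the bar
        grid = np.zeros((40, 80), dtype=bool)
        for c in range(10, 70):
            w = 2 + (c - 10) // 12  # 2..6 px
            grid[20 - w // 2 : 20 - w // 2 + w, c] = True
        skel = skeletonize(grid)
        g = build_graph(skel, cord_xy=(20, 10), scale=35.0)
        measure_thickness(grid, g)
        seg = next(iter(g.segments.values()))
        # oracle: brute-force distance transform along the same path
        from scipy.ndimage import distance_transform_edt

        edt = distance_transform_edt(grid)
        rr, cc = seg.pixel_path[:, 0], seg.pixel_path[:, 1]
        oracle = np.mean(2 * edt[rr, cc] - 1) / 35.0
        assert seg.thickness_cm == pytest.approx(oracle, rel=1e-9)

    def test_segment_outside_mask_raises(self):
        grid = draw_bar(width=3)
        skel = skeletonize(grid)
        g = build_graph(skel, cord_xy=(19, 5), scale=35.0)
        with pytest.raises(ValueError, match="inconsistent"):
            measure_thickness(np.zeros_like(grid), g)

    def test_palette_caliber_map_takes_precedence(self):
        grid = draw_bar(width=5)
        skel = skeletonize(grid)
        g = build_graph(skel, cord_xy=(19, 5), scale=35.0)
        caliber = np.where(grid, 0.123, 0.0)
        measure_thickness(grid, g, caliber_map=caliber)
        seg = next(iter(g.segments.values()))
        assert seg.thickness_cm == pytest.approx(0.123)


class TestPruneSpurs:
    def _graph_with_spur(self):
        skel = np.zeros((30, 30), dtype=bool)
        skel[15, 2:28] = True  # main line
        skel[14, 10] = False
        skel[13:15, 10] = True  # 2-px spur upward at column 10
        return build_graph(skel, cord_xy=(15, 2), scale=35.0)

    def test_short_spur_removed_and_counts_restored(self):
        g = self._graph_with_spur()
        assert len(g.branch_nodes()) == 1
        prune_spurs(g, min_length_cm=0.1)
        assert len(g.branch_nodes()) == 0
        assert len(g.end_nodes()) == 2
        assert len(g.segments) == 1

    def test_min_length_zero_is_identity(self):
        g = self._graph_with_spur()
        n_before = (len(g.segments), g.n)
        prune_spurs(g, min_length_cm=0.0)
        assert (len(g.segments), g.n) == n_before

    def test_negative_threshold_rejected(self):
        g = self._graph_with_spur()
        with pytest.raises(ValueError):
            prune_spurs(g, min_length_cm=-1.0)


class TestVesselMask:
    def test_invalid_cord_rejected(self):
        with pytest.raises(ValueError, match="cord"):
            VesselMask(grid=np.ones((5, 5), bool), cord_xy=(9, 9))

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            VesselMask(grid=np.ones((5, 5), bool), scale_px_per_cm=0.0)
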