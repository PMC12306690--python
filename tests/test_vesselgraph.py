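"""Masks → skeletons → centerline graphs with calibers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from retvasc.errors import FrameMismatch, InvalidLabel
from retvasc.synthetic import Fiber, make_tree, rasterize_fibers
from retvasc.vesselgraph import (
    build_graph,
    estimate_calibers,
    mask_to_graph,
    prune_graph,
    skeletonize,
    split_av_labels,
)


class TestSplitAVLabels:
    def test_crossing_belongs_to_both(self):
        m = np.array([[3]])
        a, v = split_av_labels(m)
        assert a[0, 0] == 1 and v[0, 0] == 1

    def test_pure_labels(self):
        m = np.array([[0, 1], [2, 3]])
        a, v = split_av_labels(m)
        assert a.tolist() == [[0, 1], [0, 1]]
        assert v.tolist() == [[0, 0], [1, 1]]

    def test_empty(self):
        a, v = split_av_labels(np.zeros((4, 4), int))
        assert a.sum() == 0 and v.sum() == 0

    def test_invalid_label(self):
        with pytest.raises(InvalidLabel):
            split_av_labels(np.array([[5]]))

    @given(
        hnp.arrays(np.int64, (12, 12), elements=st.integers(0, 3))
    )
    @settings(max_examples=50, deadline=None)
    def test_mass_conservation(self, m):
        a, v = split_av_labels(m)
        assert int(a.sum()) + int(v.sum()) == int(
            np.isin(m, (1, 2)).sum() + 2 * (m == 3).sum()
        )


class TestSkeletonize:
    def test_bar_thins_to_medial_row(self):
        m = np.zeros((40, 120), np.uint8)
        m[18:23, 10:110] = 1
        sk = skeletonize(m)
        assert 96 <= sk.sum() <= 100

    def test_empty(self):
        assert skeletonize(np.zeros((8, 8), np.uint8)).sum() == 0

    def test_disk_collapses_to_center(self):
        yy, xx = np.mgrid[0:60, 0:60]
        disk = ((xx - 30) ** 2 + (yy - 30) ** 2 <= 400).astype(np.uint8)
        assert skeletonize(disk).sum() <= 5


class TestBuildGraph:
    def test_straight_line(self):
        m = np.zeros((10, 60), np.uint8)
        m[5, 5:55] = 1
        g = build_graph(m)
        assert len(g.nodes) == 2
        assert len(g.segments) == 1
        assert g.segments[0].length == pytest.approx(49, abs=0.5)
        assert all(n.kind == "endpoint" for n in g.nodes.values())

    def test_symmetric_y(self):
        m = np.zeros((60, 60), np.uint8)
        m[30, 5:31] = 1
        for i in range(20):
            m[29 - i, 31 + i] = 1
            m[31 + i, 31 + i] = 1
        g = build_graph(m)
        kinds = [n.kind for n in g.nodes.values()]
        assert kinds.count("branchpoint") == 1
        assert kinds.count("endpoint") == 3
        assert len(g.segments) == 3
        bp = next(n for n in g.nodes.values() if n.kind == "branchpoint")
        assert bp.degree == 3

    def test_empty(self):
        g = build_graph(np.zeros((5, 5), np.uint8))
        assert not g.nodes and not g.segments

    def test_segment_endpoints_match_node_positions(self):
        m = np.zeros((60, 60), np.uint8)
        m[30, 5:55] = 1
        g = build_graph(m)
        s = g.segments[0]
        assert np.allclose(s.points[0], g.nodes[s.u].position)
        assert np.allclose(s.points[-1], g.nodes[s.v].position)

    def test_skeleton_pixels_partition(self):
        """Every skeleton pixel belongs to exactly one segment interior or
        one node; every interior segment point lies on the skeleton."""
        fibers, _ = make_tree(
            np.array([30.0, 100.0]), 0.0, 2, (80.0, 70.0), 7.0, (0.7, 0.55),
            60.0, 50.0, "artery",
        )
        mask = (rasterize_fibers(fibers, (200, 260)) >= 0.5).astype(np.uint8)
        sk = skeletonize(mask)
        g = build_graph(sk)
        seen = np.zeros_like(sk, dtype=int)
        for s in g.segments:
            for p in s.points[1:-1]:
                x, y = int(round(p[0])), int(round(p[1]))
                assert sk[y, x], "segment interior point off the skeleton"
                seen[y, x] += 1
        assert seen.max() <= 1


class TestEstimateCalibers:
    @pytest.mark.parametrize("width", [3, 5, 9, 15])
    def test_bar_width_recovery(self, width):
        f = Fiber(
            "spoke", "artery", float(width), "line",
            p0=np.array([10.0, 40.0]), p1=np.array([150.0, 60.0]),
        )
        mask = (rasterize_fibers([f], (100, 170)) >= 0.5).astype(np.uint8)
        g = mask_to_graph(mask, "artery")
        cal = np.concatenate([s.interior_calibers() for s in g.segments])
        assert np.median(cal) == pytest.approx(width, abs=1.0)

    def test_disk_center_caliber_is_diameter(self):
        yy, xx = np.mgrid[0:100, 0:100]
        R = 30
        disk = ((xx - 50) ** 2 + (yy - 50) ** 2 <= R**2).astype(np.uint8)
        g = estimate_calibers(build_graph(skeletonize(disk)), disk)
        cal = np.concatenate([s.calibers for s in g.segments])
        assert cal.max() == pytest.approx(2 * R, rel=0.08)

    def test_caliber_bounded_by_component_extent(self):
        f = Fiber("spoke", "artery", 9.0, "line",
                  p0=np.array([10.0, 20.0]), p1=np.array([120.0, 30.0]))
        mask = (rasterize_fibers([f], (60, 140)) >= 0.5).astype(np.uint8)
        g = mask_to_graph(mask, "artery")
        extent = np.hypot(*(np.ptp(np.argwhere(mask), axis=0)))
        for s in g.segments:
            assert np.all(s.calibers <= extent)

    def test_frame_mismatch(self):
        m = np.zeros((10, 60), np.uint8)
        m[5, 5:55] = 1
        g = build_graph(m)
        with pytest.raises(FrameMismatch):
            estimate_calibers(g, np.zeros((20, 20), np.uint8))


class TestPruneGraph:
    def _spurred_path(self):
        m = np.zeros((20, 220), np.uint8)
        m[10, 5:205] = 1
        m[9, 100] = 1
        m[8, 101] = 1
        m[7, 102] = 1
        return build_graph(m)

    def test_spur_removed_and_chain_merged(self):
        p = prune_graph(self._spurred_path(), 10)
        assert len(p.segments) == 1
        assert p.segments[0].length == pytest.approx(199, abs=1.5)

    def test_idempotent(self):
        p1 = prune_graph(self._spurred_path(), 10)
        p2 = prune_graph(p1, 10)
        assert len(p1.segments) == len(p2.segments)
        assert p1.segments[0].length == p2.segments[0].length

    def test_long_spur_retained(self):
        m = np.zeros((40, 220), np.uint8)
        m[20, 5:205] = 1
        for i in range(15):
            m[19 - i, 100 + i] = 1
        g = prune_graph(build_graph(m), 10)
        assert len(g.segments) == 3  # spur kept, path split at the branch


class TestBifurcationCountRecovery:
    @pytest.mark.parametrize("b", [3, 8, 15])
    def test_planted_count_recovered(self, b):
        fibers, _ = make_tree(
            np.array([40.0, 300.0]), -8.0, b, (85.0, 68.0, 95.0), 8.0,
            (0.75, 0.6), 60.0, 50.0, "artery",
        )
        shape = (600, 700)
        mask = (rasterize_fibers(fibers, shape) >= 0.5).astype(np.uint8)
        g = mask_to_graph(mask, "artery")
        assert g.n_branchpoints == b
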