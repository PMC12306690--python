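"""The 24-feature vascular panel: closed forms, oracles, recovery."""

import numpy as np
import pytest

from retvasc.biomarkers import (
    FEATURE_NAMES,
    CREConfig,
    FeatureSet,
    arc_chord_tortuosity,
    bifurcation_angles,
    caliber_stats,
    compute_feature_set,
    cre,
    curvature_profile,
    inflection_count,
    knudtson_combine,
    length_weighted_tortuosity,
    segment_curvature_feature,
    select_zone_widths,
    temporal_angle,
    vascular_density,
)
from retvasc.errors import ArcadeNotFound, EmptyRegion, NoPoints, ZeroChord
from retvasc.regions import DiscGeometry, RegionMask, measurement_zone
from retvasc.synthetic import Fiber, rasterize_fibers
from retvasc.vesselgraph import Segment, mask_to_graph


def polyline(f, t0, t1, n=2000):
    t = np.linspace(t0, t1, n)
    return np.column_stack(f(t))


class TestTortuosity:
    def test_straight_is_one(self):
        pts = np.column_stack([np.linspace(0, 100, 300), np.full(300, 5.0)])
        assert arc_chord_tortuosity(pts) == 1.0

    def test_semicircle(self):
        pts = polyline(lambda t: (100 * np.cos(t), 100 * np.sin(t)), 0, np.pi)
        assert arc_chord_tortuosity(pts) == pytest.approx(np.pi / 2, abs=1e-3)

    def test_sinusoid_against_quadrature(self):
        A, lam = 8.0, 90.0
        x = np.linspace(0, 270, 20000)
        y = A * np.sin(2 * np.pi * x / lam)
        pts = np.column_stack([x, y])
        # independent oracle: quadrature of the analytic arc-length integrand
        arc = np.trapezoid(np.sqrt(1 + (A * 2 * np.pi / lam * np.cos(2 * np.pi * x / lam)) ** 2), x)
        expect = arc / 270.0
        assert arc_chord_tortuosity(pts) == pytest.approx(expect, rel=5e-3)

    def test_zero_chord(self):
        t = np.linspace(0, 2 * np.pi, 100)
        with pytest.raises(ZeroChord):
            arc_chord_tortuosity(np.column_stack([np.cos(t), np.sin(t)]))


class TestLengthWeightedTortuosity:
    @staticmethod
    def _segment_with(length, tortuosity):
        """V-shaped polyline with exact arc length and arc/chord ratio."""
        half = length / 2.0
        chord = length / tortuosity
        h = np.sqrt(half**2 - (chord / 2) ** 2)
        pts = np.array([[0, 0], [chord / 2, h], [chord, 0]], dtype=float)
        return Segment(points=pts, u=0, v=1)

    def test_weighted_mean(self):
        segs = [self._segment_with(100, 1.0), self._segment_with(300, 1.2)]
        assert length_weighted_tortuosity(segs) == pytest.approx(1.15, abs=1e-6)

    def test_all_straight(self):
        segs = [self._segment_with(50, 1.0), self._segment_with(70, 1.0)]
        assert length_weighted_tortuosity(segs) == pytest.approx(1.0, abs=1e-9)

    def test_equal_lengths_reduce_to_plain_mean(self):
        segs = [self._segment_with(100, 1.1), self._segment_with(100, 1.3)]
        expect = np.mean([arc_chord_tortuosity(s.points) for s in segs])
        assert length_weighted_tortuosity(segs) == pytest.approx(expect, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            length_weighted_tortuosity([])


class TestCurvature:
    def test_arc_radius_200(self):
        pts = polyline(lambda t: (500 + 200 * np.cos(t), 500 + 200 * np.sin(t)), 0.2, 1.8)
        assert segment_curvature_feature(pts) == pytest.approx(5.0, rel=0.02)

    def test_straight_is_zero(self):
        pts = np.column_stack([np.linspace(0, 300, 600), np.linspace(0, 40, 600)])
        assert segment_curvature_feature(pts) < 0.05

    def test_radius_scaling_law(self):
        f1 = segment_curvature_feature(
            polyline(lambda t: (300 * np.cos(t), 300 * np.sin(t)), 0.2, 1.4)
        )
        f2 = segment_curvature_feature(
            polyline(lambda t: (600 * np.cos(t), 600 * np.sin(t)), 0.2, 1.4)
        )
        assert f1 / f2 == pytest.approx(2.0, rel=0.02)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            curvature_profile(np.array([[0, 0], [1, 1], [2, 2]]))


class TestInflectionCount:
    def test_straight_and_single_arc_zero(self):
        line = np.column_stack([np.linspace(0, 250, 400), np.zeros(400)])
        arc = polyline(lambda t: (300 * np.cos(t), 300 * np.sin(t)), 0.2, 1.2)
        assert inflection_count(line) == 0
        assert inflection_count(arc) == 0

    def test_one_sine_period(self):
        x = np.linspace(0, 200, 200)
        pts = np.column_stack([x, 12 * np.sin(2 * np.pi * x / 200)])
        assert inflection_count(pts) == 1

    def test_s_curve(self):
        t = np.linspace(0.1, 1.4, 500)
        up = np.column_stack([200 * np.sin(t), 200 - 200 * np.cos(t)])
        down = np.column_stack(
            [up[-1, 0] + 200 * np.sin(t), up[-1, 1] + 200 * np.cos(t) - 200 * np.cos(t[0])]
        )
        # join two opposite arcs smoothly-ish
        pts = np.vstack([up, down + (up[-1] - down[0])])
        assert inflection_count(pts) == 1


class TestKnudtson:
    def test_artery_pair(self):
        assert knudtson_combine(10, 10, "artery") == pytest.approx(12.445, abs=1e-3)

    def test_vein_pair(self):
        assert knudtson_combine(10, 10, "vein") == pytest.approx(13.435, abs=1e-3)

    def test_zero_width_passthrough_scaled(self):
        assert knudtson_combine(0, 7, "artery") == pytest.approx(0.88 * 7, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            knudtson_combine(-1, 5, "artery")


def cre_oracle(widths, kind, n=6):
    """Independent brute-force pairing recursion (sort, pair extremes, carry
    the median when odd), written without reference to the implementation."""
    c = {"artery": 0.88, "vein": 0.95}[kind]
    ws = sorted(widths, reverse=True)[:n]
    while len(ws) > 1:
        ws = sorted(ws)
        out = []
        while len(ws) > 1:
            lo = ws.pop(0)
            hi = ws.pop(-1)
            out.append(c * np.sqrt(lo**2 + hi**2))
        out.extend(ws)  # odd count: median element carried
        ws = out
    return ws[0]


class TestCRE:
    def test_six_equal_artery_widths(self):
        assert cre([10] * 6, "artery") == pytest.approx(17.4845, abs=0.01)
        assert cre([10] * 6, "artery") == pytest.approx(
            cre_oracle([10] * 6, "artery"), abs=1e-9
        )

    def test_single_width_is_identity(self):
        assert cre([7.5], "artery") == 7.5

    def test_permutation_invariance(self):
        ws = [12.0, 3.0, 8.0, 10.0, 6.0, 4.0]
        assert cre(ws, "vein") == pytest.approx(cre(ws[::-1], "vein"), abs=1e-12)

    def test_matches_oracle_on_sampled_multisets(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            k = int(rng.integers(1, 7))
            ws = rng.integers(1, 21, size=k).astype(float).tolist()
            kind = "artery" if rng.integers(2) else "vein"
            assert cre(ws, kind) == pytest.approx(cre_oracle(ws, kind), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cre([], "artery")


class TestSelectZoneWidths:
    def test_radial_spokes_recovered(self):
        disc = DiscGeometry(300, 300, 100.0)
        widths = [12.0, 10.0, 8.0, 6.0, 4.0, 3.0]
        fibers = [
            Fiber(
                "spoke", "artery", w, "line",
                p0=np.array([300 + 70 * np.cos(a), 300 + 70 * np.sin(a)]),
                p1=np.array([300 + 190 * np.cos(a), 300 + 190 * np.sin(a)]),
            )
            for w, a in zip(widths, np.radians([0, 60, 120, 180, 240, 300]))
        ]
        mask = (rasterize_fibers(fibers, (600, 600)) >= 0.5).astype(np.uint8)
        g = mask_to_graph(mask, "artery")
        zone = measurement_zone(disc, (600, 600))
        got = select_zone_widths(g, zone, 6)
        assert len(got) == 6
        assert np.allclose(sorted(got, reverse=True), widths, atol=1.0)

    def test_empty_zone(self, default_graphs):
        artery, _ = default_graphs
        empty = RegionMask(np.zeros(artery.frame_shape, bool), "empty")
        assert select_zone_widths(artery, empty, 6) == []

    def test_returns_fewer_when_fewer_cross(self):
        disc = DiscGeometry(300, 300, 100.0)
        f = Fiber("spoke", "artery", 8.0, "line",
                  p0=np.array([370.0, 300.0]), p1=np.array([490.0, 300.0]))
        mask = (rasterize_fibers([f], (600, 600)) >= 0.5).astype(np.uint8)
        g = mask_to_graph(mask, "artery")
        zone = measurement_zone(disc, (600, 600))
        assert len(select_zone_widths(g, zone, 6)) == 1


class TestBifurcationAngles:
    @pytest.mark.parametrize("half_angle,expect", [(45, 90), (30, 60)])
    def test_symmetric_y(self, half_angle, expect):
        a = np.radians(half_angle)
        root = np.array([40.0, 150.0])
        mid = np.array([140.0, 150.0])
        fibers = [
            Fiber("branch", "artery", 8.0, "line", p0=root, p1=mid),
            Fiber("branch", "artery", 5.0, "line",
                  p0=mid, p1=mid + 90 * np.array([np.cos(a), -np.sin(a)])),
            Fiber("branch", "artery", 5.0, "line",
                  p0=mid, p1=mid + 90 * np.array([np.cos(a), np.sin(a)])),
        ]
        mask = (rasterize_fibers(fibers, (300, 300)) >= 0.5).astype(np.uint8)
        g = mask_to_graph(mask, "artery")
        angles, diag = bifurcation_angles(g)
        assert diag["n_bifurcations"] == 1
        assert len(angles) == 1
        assert angles[0] == pytest.approx(expect, abs=2.0)

    def test_planted_tree_recovery(self, default_scene, default_graphs):
        for cls, g in zip(("artery", "vein"), default_graphs):
            angles, diag = bifurcation_angles(g)
            planted = sorted(default_scene.truth.bifurcation_angles[cls])
            assert diag["n_bifurcations"] == len(planted)
            err = np.abs(np.array(sorted(angles)) - np.array(planted))
            assert err.mean() <= 5.0


class TestTemporalAngle:
    def test_planted_arcade_angles(self, default_scene, default_graphs):
        scene = default_scene
        artery, vein = default_graphs
        disc = DiscGeometry(
            scene.config.disc_center[0], scene.config.disc_center[1], scene.config.dd
        )
        fovea = (scene.fovea.x, scene.fovea.y)
        ta = temporal_angle(artery, disc, fovea)
        tv = temporal_angle(vein, disc, fovea)
        assert ta == pytest.approx(scene.truth.features["temporal_angle_A"], abs=3)
        assert tv == pytest.approx(scene.truth.features["temporal_angle_V"], abs=3)

    def test_axis_bisects_symmetric_arcades(self, default_scene, default_graphs):
        # default scene plants equal superior/inferior angles; check the
        # arcade picks land symmetrically about the disc-fovea axis
        scene = default_scene
        cfg = scene.config
        assert cfg.artery.arcade_angles_deg[0] == cfg.artery.arcade_angles_deg[1]

    def test_nasal_only_graph_missing(self):
        disc = DiscGeometry(300, 300, 100.0)
        f = Fiber("spoke", "artery", 8.0, "line",
                  p0=np.array([230.0, 300.0]), p1=np.array([110.0, 300.0]))
        mask = (rasterize_fibers([f], (600, 600)) >= 0.5).astype(np.uint8)
        g = mask_to_graph(mask, "artery")
        with pytest.raises(ArcadeNotFound):
            temporal_angle(g, disc, (450.0, 300.0))


class TestVascularDensity:
    def test_full_cover(self):
        region = RegionMask(np.ones((10, 10), bool), "r")
        assert vascular_density(np.ones((10, 10)), region) == 100.0

    def test_empty_mask(self):
        region = RegionMask(np.ones((10, 10), bool), "r")
        assert vascular_density(np.zeros((10, 10)), region) == 0.0

    def test_half_cover(self):
        region = RegionMask(np.ones((10, 10), bool), "r")
        mask = np.zeros((10, 10))
        mask[:5] = 1
        assert vascular_density(mask, region) == 50.0

    def test_empty_region_raises(self):
        with pytest.raises(EmptyRegion):
            vascular_density(np.ones((5, 5)), RegionMask(np.zeros((5, 5), bool), "r"))


class TestCaliberStats:
    def test_single_bar(self):
        f = Fiber("spoke", "artery", 9.0, "line",
                  p0=np.array([15.0, 40.0]), p1=np.array([175.0, 55.0]))
        mask = (rasterize_fibers([f], (100, 200)) >= 0.5).astype(np.uint8)
        g = mask_to_graph(mask, "artery")
        region = RegionMask(np.ones((100, 200), bool), "all")
        med, std = caliber_stats(g, region)
        assert med == pytest.approx(9, abs=1)
        assert std <= 0.6

    def test_pooled_median_over_several_bars(self):
        fibers = [
            Fiber("spoke", "artery", w, "line",
                  p0=np.array([15.0, y]), p1=np.array([175.0, y]))
            for w, y in ((5.0, 30.0), (7.0, 70.0), (9.0, 110.0))
        ]
        mask = (rasterize_fibers(fibers, (150, 200)) >= 0.5).astype(np.uint8)
        g = mask_to_graph(mask, "artery")
        med, _ = caliber_stats(g, RegionMask(np.ones((150, 200), bool), "all"))
        assert med == pytest.approx(7, abs=1)

    def test_empty_region_missing(self, default_graphs):
        artery, _ = default_graphs
        with pytest.raises(NoPoints):
            caliber_stats(artery, RegionMask(np.zeros(artery.frame_shape, bool), "e"))


class TestComputeFeatureSet:
    def test_canonical_key_set(self, default_measured_features):
        assert set(default_measured_features.values) == set(FEATURE_NAMES)
        assert len(FEATURE_NAMES) == 24

    def test_no_bifurcations_yields_zero_count_and_missing_angles(self, default_scene):
        scene = default_scene
        # graphs from spokes only: no degree-3 nodes
        f = Fiber("spoke", "artery", 8.0, "line",
                  p0=np.array([360.0, 512.0]), p1=np.array([200.0, 512.0]))
        mask = (rasterize_fibers([f], scene.artery_mask.shape) >= 0.5).astype(np.uint8)
        g = mask_to_graph(mask, "artery")
        disc = DiscGeometry(328, 512, 131.0)
        fs = compute_feature_set(
            g, g, mask, mask, disc, (scene.fovea.x, scene.fovea.y), scene.bounds_truth
        )
        assert fs["n_bifurcations_A"] == 0
        assert fs["bif_angle_mean_A"] is None
        assert "bif_angle_mean_A" in fs.reasons

    def test_missing_never_encoded_as_zero(self):
        fs = FeatureSet()
        fs.mark_missing("cre_A", "no vessels")
        assert fs["cre_A"] is None
        s = fs.to_series()
        assert np.isnan(s["cre_A"])
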