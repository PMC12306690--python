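"""The 24-feature vascular biomarker panel.

Per vessel class (artery A, vein V) the panel comprises: temporal arcade
opening angle (degrees), central retinal equivalent CRE (px, Knudtson
pairing of the six largest peripapillary calibers), vascular density (% of
the field of view), caliber median and standard deviation (px), arc/chord
tortuosity (median over segments and length-weighted), curvature median
(10^-3 / px), inflection count median, bifurcation angle mean and median
(degrees) and bifurcation count — 24 named values in total.

Measurements are taken on centerline graphs whose polylines are resampled
and smoothed before metric evaluation (see `_geometry.canonical_polyline`);
raw pixel chains would otherwise inflate arc lengths and curvature through
staircase quantization.  Every feature can be missing (None), never 0, when
its inputs are degenerate; a reason string is recorded per missing feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from ._geometry import (
    canonical_polyline,
    cumulative_arclength,
    polyline_length,
    signed_curvature,
)
from .errors import (
    ArcadeNotFound,
    EmptyRegion,
    FrameMismatch,
    NoPoints,
    ZeroChord,
)
from .preprocess import FundusBounds
from .regions import DiscGeometry, RegionConfig, RegionMask, fov_region, measurement_zone
from .vesselgraph import Segment, VesselGraph

__all__ = [
    "FEATURE_NAMES",
    "FeatureSet",
    "CREConfig",
    "BiomarkerConfig",
    "arc_chord_tortuosity",
    "length_weighted_tortuosity",
    "curvature_profile",
    "segment_curvature_feature",
    "inflection_count",
    "knudtson_combine",
    "cre",
    "select_zone_widths",
    "bifurcation_angles",
    "temporal_angle",
    "vascular_density",
    "caliber_stats",
    "compute_feature_set",
]

_PER_CLASS = [
    "temporal_angle",
    "cre",
    "vascular_density",
    "caliber_med",
    "caliber_std",
    "tortuosity_med",
    "curvature_med",
    "inflection_count_med",
    "tortuosity_lw",
    "bif_angle_mean",
    "bif_angle_med",
    "n_bifurcations",
]

#: The canonical 24 feature names (per-class panel x {A, V}).
FEATURE_NAMES: list[str] = [f"{name}_{c}" for name in _PER_CLASS for c in ("A", "V")]


@dataclass
class FeatureSet:
    """24 named biomarker values; missing values are None with a reason."""

    values: dict[str, Optional[float]] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name in FEATURE_NAMES:
            self.values.setdefault(name, None)
        extra = set(self.values) - set(FEATURE_NAMES)
        if extra:
            raise ValueError(f"unknown feature names: {sorted(extra)}")

    def __getitem__(self, key: str) -> Optional[float]:
        return self.values[key]

    def __setitem__(self, key: str, value: Optional[float]) -> None:
        if key not in FEATURE_NAMES:
            raise KeyError(key)
        self.values[key] = value

    def mark_missing(self, key: str, reason: str) -> None:
        self[key] = None
        self.reasons[key] = reason

    def to_series(self) -> pd.Series:
        return pd.Series(
            {k: (np.nan if self.values[k] is None else self.values[k]) for k in FEATURE_NAMES},
            dtype=float,
        )

    @classmethod
    def from_mapping(cls, d: dict) -> "FeatureSet":
        vals = {
            k: (None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v))
            for k, v in d.items()
            if k in FEATURE_NAMES
        }
        return cls(values=vals)


@dataclass
class CREConfig:
    """Constants of the revised (Knudtson) central retinal equivalents."""

    artery_constant: float = 0.88
    vein_constant: float = 0.95
    n_vessels: int = 6

    def __post_init__(self):
        if not (0 < self.artery_constant <= 1 and 0 < self.vein_constant <= 1):
            raise ValueError("branch constants must be in (0, 1]")
        if self.n_vessels < 1:
            raise ValueError("n_vessels must be >= 1")

    def constant(self, kind: str) -> float:
        if kind == "artery":
            return self.artery_constant
        if kind == "vein":
            return self.vein_constant
        raise ValueError(f"kind must be 'artery' or 'vein', got {kind!r}")


@dataclass
class BiomarkerConfig:
    cre: CREConfig = field(default_factory=CREConfig)
    regions: RegionConfig = field(default_factory=RegionConfig)
    min_segment_length: float = 20.0  # px; shorter inter-branch stubs are noise
    # curvature/inflection need interior samples clear of both ends by the
    # full filter span; shorter segments would measure junction hooks
    curvature_min_length: float = 80.0  # px
    resample_spacing: float = 1.0  # px between canonical centerline samples
    smooth_window: int = 29  # moving-average window (samples)
    deriv_window: int = 25  # Savitzky-Golay window for derivatives (samples)
    inflection_smooth: int = 9  # extra curvature smoothing for sign counting
    inflection_floor: float = 5e-4  # px^-1; |kappa| below this is noise
    direction_arclength: float = 60.0  # px over which branch directions are averaged

    def scaled(self, factor: float) -> "BiomarkerConfig":
        """Config for a frame rescaled by `factor`.

        Every pixel-valued knob scales with the frame so the measurement is
        the same computation on the rescaled lattice; windows counted in
        samples stay fixed because the sample spacing itself scales.
        """
        return replace(
            self,
            min_segment_length=self.min_segment_length * factor,
            curvature_min_length=self.curvature_min_length * factor,
            resample_spacing=self.resample_spacing * factor,
            direction_arclength=self.direction_arclength * factor,
            inflection_floor=self.inflection_floor / factor,
        )


# ---------------------------------------------------------------------------
# segment-level primitives


def arc_chord_tortuosity(points: np.ndarray) -> float:
    """Arc length / chord length of a polyline; >= 1, dimensionless."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord < 1e-9:
        raise ZeroChord("closed segment has no chord")
    return max(polyline_length(pts) / chord, 1.0)


def length_weighted_tortuosity(segments: Sequence[Segment]) -> float:
    """Mean segment tortuosity weighted by segment arc length."""
    if not segments:
        raise ValueError("no segments")
    num = den = 0.0
    for seg in segments:
        tort = arc_chord_tortuosity(seg.points)
        length = seg.length
        num += length * tort
        den += length
    if den <= 0:
        raise ValueError("zero total length")
    return num / den


def curvature_profile(
    points: np.ndarray,
    smooth_window: int = 29,
    spacing: float = 1.0,
    deriv_window: int = 25,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed curvature along a polyline, on the canonical resampled line.

    Returns (resampled_points, kappa) where kappa is in 1/px.  Requires at
    least 5 input points.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 5:
        raise ValueError("too short for curvature")
    canon = canonical_polyline(pts, spacing=spacing, window=smooth_window)
    if len(canon) < 5:
        raise ValueError("too short for curvature")
    return canon, signed_curvature(canon, window=deriv_window)


def segment_curvature_feature(
    points: np.ndarray,
    smooth_window: int = 29,
    spacing: float = 1.0,
    deriv_window: int = 25,
) -> float:
    """Per-segment curvature feature: mean |kappa| x 10^3 (units 10^-3/px).

    Samples inside the smoothing/derivative filter span of either end are
    excluded when the segment is long enough — end handling attenuates the
    curvature there — with a lighter max(10%, ~8 px) trim on short segments
    where the full span would leave nothing.
    """
    _, k = curvature_profile(points, smooth_window, spacing, deriv_window)
    m = _end_trim(len(k), smooth_window, deriv_window, spacing)
    core = k[m:-m] if len(k) > 2 * m else k
    return float(np.abs(core).mean() * 1e3)


def _end_trim(n: int, smooth_window: int, deriv_window: int, spacing: float) -> int:
    full = (smooth_window + deriv_window) // 2  # combined filter half-spans
    if n > 2 * full + 10:
        return full
    return max(1, n // 10, int(round(8.0 / max(spacing, 1e-6))))


def inflection_count(
    points: np.ndarray,
    smooth_window: int = 29,
    spacing: float = 1.0,
    extra_smooth: int = 9,
    floor: float = 5e-4,
    deriv_window: int = 25,
) -> int:
    """Number of sign changes of the smoothed signed curvature.

    Curvature magnitudes below `floor` (1/px) are treated as straight; a
    sign change is counted only between excursions that exceed the floor on
    both sides (hysteresis), which suppresses quantization chatter.
    """
    _, k = curvature_profile(points, smooth_window, spacing, deriv_window)
    if extra_smooth > 1 and len(k) > extra_smooth:
        k = uniform_filter1d(k, extra_smooth)
    m = _end_trim(len(k), smooth_window, deriv_window, spacing)
    core = k[m:-m] if len(k) > 2 * m else k
    signs = np.where(core > floor, 1, np.where(core < -floor, -1, 0))
    signs = signs[signs != 0]
    if len(signs) < 2:
        return 0
    return int(np.sum(np.diff(signs) != 0))


# ---------------------------------------------------------------------------
# central retinal equivalents


def knudtson_combine(w1: float, w2: float, kind: str, config: CREConfig | None = None) -> float:
    """Combine a branch pair: constant(kind) * sqrt(w1^2 + w2^2)."""
    cfg = config or CREConfig()
    if w1 < 0 or w2 < 0:
        raise ValueError("widths must be non-negative")
    return cfg.constant(kind) * float(np.hypot(w1, w2))


def cre(widths: Sequence[float], kind: str, config: CREConfig | None = None) -> float:
    """Central retinal equivalent by iterative Knudtson pairing.

    The `n_vessels` largest widths are reduced by repeatedly sorting and
    combining the largest with the smallest; with an odd count the median
    element is carried to the next round unchanged.  A single width is its
    own equivalent.
    """
    cfg = config or CREConfig()
    ws = sorted((float(w) for w in widths), reverse=True)[: cfg.n_vessels]
    if not ws:
        raise ValueError("no widths")
    while len(ws) > 1:
        ws.sort()
        nxt = []
        n = len(ws)
        for i in range(n // 2):
            nxt.append(knudtson_combine(ws[n - 1 - i], ws[i], kind, cfg))
        if n % 2:
            nxt.append(ws[n // 2])
        ws = nxt
    return ws[0]


def select_zone_widths(
    graph: VesselGraph, zone: RegionMask, n: int
) -> list[float]:
    """Representative widths of segments crossing a measurement zone.

    Per segment with centerline points inside the zone, the representative
    width is the median caliber over its in-zone points; the `n` largest
    such widths are returned (fewer if fewer segments cross the zone).
    """
    h, w = zone.mask.shape
    widths = []
    for seg in graph.segments:
        if seg.calibers is None:
            raise ValueError("calibers not estimated")
        pts = np.round(np.asarray(seg.points)).astype(int)
        ok = (pts[:, 0] >= 0) & (pts[:, 0] < w) & (pts[:, 1] >= 0) & (pts[:, 1] < h)
        inz = np.zeros(len(pts), bool)
        inz[ok] = zone.mask[pts[ok, 1], pts[ok, 0]]
        if inz.sum() == 0:
            continue
        widths.append(float(np.median(seg.calibers[inz])))
    return sorted(widths, reverse=True)[:n]


# ---------------------------------------------------------------------------
# bifurcations


def _initial_direction(
    seg: Segment, from_start: bool, skip: float, window: float,
    far_margin: float = 0.0,
) -> np.ndarray:
    """Unit direction of the branch leaving a node: the chord between arc
    lengths [skip, skip+window] from the node, skipping the junction-
    distorted first stretch of skeleton (about one parent caliber) and
    stopping `far_margin` short of the far end (tapered tips wander)."""
    pts = seg.points if from_start else seg.points[::-1]
    s = cumulative_arclength(pts)
    i0 = int(np.searchsorted(s, min(skip, s[-1] * 0.4)))
    i1 = int(np.searchsorted(s, min(skip + window, s[-1] - far_margin)))
    i1 = max(i1, i0 + 1)
    i1 = min(i1, len(pts) - 1)
    i0 = min(i0, i1 - 1)
    window_pts = pts[i0 : i1 + 1]
    if len(window_pts) >= 4:
        # total-least-squares direction: principal axis of the window,
        # oriented away from the node
        centered = window_pts - window_pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        d = vt[0]
        if np.dot(d, pts[i1] - pts[i0]) < 0:
            d = -d
    else:
        d = pts[i1] - pts[i0]
    n = np.linalg.norm(d)
    return d / n if n > 0 else np.array([0.0, 0.0])


def _local_caliber(seg: Segment, from_start: bool, arclength: float) -> float:
    if seg.calibers is None:
        return float("nan")
    cal = seg.calibers if from_start else seg.calibers[::-1]
    pts = seg.points if from_start else seg.points[::-1]
    s = cumulative_arclength(pts)
    sel = s <= max(arclength, s[min(1, len(s) - 1)])
    return float(np.median(cal[sel]))


def bifurcation_angles(
    graph: VesselGraph, config: BiomarkerConfig | None = None
) -> tuple[list[float], dict]:
    """Angle between the two daughter branches at each degree-3 branchpoint.

    Daughters are the two thinner incident branches by local caliber (ties
    broken by the smaller angle to the parent direction); the angle is
    measured between their initial direction vectors, averaged over the
    first `direction_arclength` px of centerline.  Nodes of degree >= 4 are
    skipped and counted in the returned diagnostics.
    """
    cfg = config or BiomarkerConfig()
    angles: list[float] = []
    diagnostics = {"skipped_degree_ge4": 0, "n_bifurcations": 0}
    for node in graph.nodes.values():
        if node.kind != "branchpoint":
            continue
        ends = []
        for seg in graph.segments:
            if seg.closed:
                continue
            if seg.u == node.id:
                ends.append((seg, True))
            if seg.v == node.id:
                ends.append((seg, False))
        if len(ends) >= 4:
            diagnostics["skipped_degree_ge4"] += 1
            continue
        if len(ends) != 3:
            continue
        diagnostics["n_bifurcations"] += 1
        cals = [_local_caliber(s, fs, 20.0) for s, fs in ends]
        # skip the junction-distorted stretch (~ the thickest local caliber)
        skip = max(c for c in cals if np.isfinite(c)) if cals else 0.0
        dirs = [
            _initial_direction(s, fs, skip, cfg.direction_arclength, far_margin=c)
            for (s, fs), c in zip(ends, cals)
        ]
        order = np.argsort(cals, kind="stable")
        d1, d2 = dirs[order[0]], dirs[order[1]]
        # tie between 2nd and 3rd thinnest: prefer the branch closer in
        # direction to the parent's opposite (smaller branch angle to parent)
        if abs(cals[order[1]] - cals[order[2]]) < 1e-9:
            parent_dir = dirs[order[2]]
            cand = [order[1], order[2]]
            scores = [float(np.dot(dirs[i], -parent_dir)) for i in cand]
            d2 = dirs[cand[int(np.argmax(scores))]]
        cosang = float(np.clip(np.dot(d1, d2), -1.0, 1.0))
        angles.append(float(np.degrees(np.arccos(cosang))))
    return angles, diagnostics


# ---------------------------------------------------------------------------
# region-scoped features


def temporal_angle(
    graph: VesselGraph,
    disc: DiscGeometry,
    fovea: tuple[float, float],
    config: RegionConfig | None = None,
) -> float:
    """Opening angle of the temporal arcades, at the disc center.

    Centerline crossings of the circle of radius arcade_circle_radius * DD
    about the disc center are collected on the temporal side (the half-plane
    containing the fovea); the maximum-caliber crossing above and below the
    disc-fovea axis are the arcade representatives, and the returned value
    is the angle they subtend at the disc center.
    """
    cfg = config or RegionConfig()
    c = disc.center
    radius = cfg.arcade_circle_radius * disc.dd
    axis = np.array([fovea[0], fovea[1]], float) - c
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("fovea coincides with disc center")
    axis = axis / norm
    above, below = [], []  # (caliber, unit radial vector)
    for seg in graph.segments:
        pts = np.asarray(seg.points, float)
        if len(pts) < 2:
            continue
        rr = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) - radius
        sign_change = np.nonzero(np.diff(np.signbit(rr)))[0]
        for i in sign_change:
            t = rr[i] / (rr[i] - rr[i + 1])
            p = pts[i] + t * (pts[i + 1] - pts[i])
            v = p - c
            if np.dot(v, axis) <= 0:
                continue  # nasal side
            cal = 0.0
            if seg.calibers is not None:
                cal = float(seg.calibers[i] + t * (seg.calibers[i + 1] - seg.calibers[i]))
            side = axis[0] * v[1] - axis[1] * v[0]  # y-down frame
            (above if side < 0 else below).append((cal, v / np.linalg.norm(v)))
    if not above or not below:
        raise ArcadeNotFound(
            "no arcade crossing on the "
            + ("superior" if not above else "inferior")
            + " temporal side"
        )
    va = max(above, key=lambda t: t[0])[1]
    vb = max(below, key=lambda t: t[0])[1]
    return float(np.degrees(np.arccos(np.clip(np.dot(va, vb), -1.0, 1.0))))


def vascular_density(mask: np.ndarray, region: RegionMask) -> float:
    """Percentage of region pixels covered by the vessel mask."""
    m = np.asarray(mask).astype(bool)
    if m.shape != region.mask.shape:
        raise FrameMismatch("mask and region have different shapes")
    denom = region.area
    if denom == 0:
        raise EmptyRegion(f"region {region.name!r} is empty")
    return 100.0 * float((m & region.mask).sum()) / denom


def caliber_stats(graph: VesselGraph, region: RegionMask) -> tuple[float, float]:
    """Median and standard deviation of non-tip centerline calibers in region."""
    h, w = region.mask.shape
    pool = []
    for seg in graph.segments:
        if seg.calibers is None:
            raise ValueError("calibers not estimated")
        keep = np.ones(len(seg.points), bool) if seg.tip is None else ~seg.tip
        pts = np.round(np.asarray(seg.points)).astype(int)
        ok = keep & (pts[:, 0] >= 0) & (pts[:, 0] < w) & (pts[:, 1] >= 0) & (pts[:, 1] < h)
        inr = np.zeros(len(pts), bool)
        inr[ok] = region.mask[pts[ok, 1], pts[ok, 0]]
        if inr.any():
            pool.append(seg.calibers[inr])
    if not pool:
        raise NoPoints("no centerline points in region")
    allc = np.concatenate(pool)
    return float(np.median(allc)), float(allc.std())


# ---------------------------------------------------------------------------
# the full panel


def _eligible_segments(graph: VesselGraph, min_length: float) -> list[Segment]:
    return [s for s in graph.segments if not s.closed and s.length >= min_length]


def compute_feature_set(
    artery: VesselGraph,
    vein: VesselGraph,
    artery_mask: np.ndarray,
    vein_mask: np.ndarray,
    disc: DiscGeometry,
    fovea: tuple[float, float],
    bounds: FundusBounds,
    config: BiomarkerConfig | None = None,
) -> FeatureSet:
    """Compute all 24 features in the canonical frame.

    Densities and caliber statistics are scoped to the FOV excluding the
    disc; CRE to the peripapillary measurement zone.  Degenerate inputs
    yield missing values with reasons, never exceptions.
    """
    cfg = config or BiomarkerConfig()
    fs = FeatureSet()
    frame = tuple(np.asarray(artery_mask).shape[:2])
    fov = fov_region(bounds, disc, frame)
    zone = measurement_zone(disc, frame, cfg.regions)

    for suffix, graph, mask, kind in (
        ("A", artery, artery_mask, "artery"),
        ("V", vein, vein_mask, "vein"),
    ):
        segs = _eligible_segments(graph, cfg.min_segment_length)

        # density
        try:
            fs[f"vascular_density_{suffix}"] = vascular_density(mask, fov)
        except EmptyRegion as e:
            fs.mark_missing(f"vascular_density_{suffix}", str(e))

        # caliber stats
        try:
            med, std = caliber_stats(graph, fov)
            fs[f"caliber_med_{suffix}"] = med
            fs[f"caliber_std_{suffix}"] = std
        except (NoPoints, ValueError) as e:
            fs.mark_missing(f"caliber_med_{suffix}", str(e))
            fs.mark_missing(f"caliber_std_{suffix}", str(e))

        # tortuosity / curvature / inflections over canonical centerlines
        torts, lengths, curvs, inflections = [], [], [], []
        for seg in segs:
            canon = canonical_polyline(
                seg.points, spacing=cfg.resample_spacing, window=cfg.smooth_window
            )
            try:
                torts.append(arc_chord_tortuosity(canon))
                lengths.append(polyline_length(canon))
            except ZeroChord:
                continue
            if seg.length < cfg.curvature_min_length:
                continue
            try:
                curvs.append(
                    segment_curvature_feature(
                        seg.points,
                        cfg.smooth_window,
                        cfg.resample_spacing,
                        cfg.deriv_window,
                    )
                )
                inflections.append(
                    inflection_count(
                        seg.points,
                        cfg.smooth_window,
                        cfg.resample_spacing,
                        cfg.inflection_smooth,
                        cfg.inflection_floor,
                        cfg.deriv_window,
                    )
                )
            except ValueError:
                pass
        if torts:
            fs[f"tortuosity_med_{suffix}"] = float(np.median(torts))
            tw = np.array(torts) * np.array(lengths)
            fs[f"tortuosity_lw_{suffix}"] = float(tw.sum() / np.sum(lengths))
        else:
            fs.mark_missing(f"tortuosity_med_{suffix}", "no eligible segments")
            fs.mark_missing(f"tortuosity_lw_{suffix}", "no eligible segments")
        if curvs:
            fs[f"curvature_med_{suffix}"] = float(np.median(curvs))
        else:
            fs.mark_missing(f"curvature_med_{suffix}", "no eligible segments")
        if inflections:
            fs[f"inflection_count_med_{suffix}"] = float(np.median(inflections))
        else:
            fs.mark_missing(f"inflection_count_med_{suffix}", "no eligible segments")

        # CRE
        widths = select_zone_widths(graph, zone, cfg.cre.n_vessels)
        if widths:
            fs[f"cre_{suffix}"] = cre(widths, kind, cfg.cre)
        else:
            fs.mark_missing(f"cre_{suffix}", "no vessels cross the measurement zone")

        # bifurcations
        angles, diag = bifurcation_angles(graph, cfg)
        fs[f"n_bifurcations_{suffix}"] = float(diag["n_bifurcations"])
        if angles:
            fs[f"bif_angle_mean_{suffix}"] = float(np.mean(angles))
            fs[f"bif_angle_med_{suffix}"] = float(np.median(angles))
        else:
            fs.mark_missing(f"bif_angle_mean_{suffix}", "no degree-3 branchpoints")
            fs.mark_missing(f"bif_angle_med_{suffix}", "no degree-3 branchpoints")

        # temporal angle
        try:
            fs[f"temporal_angle_{suffix}"] = temporal_angle(
                graph, disc, fovea, cfg.regions
            )
        except (ArcadeNotFound, ValueError) as e:
            fs.mark_missing(f"temporal_angle_{suffix}", str(e))

    return fs
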