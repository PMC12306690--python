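"""Synthetic fundus scenes with fully analytic ground truth.

A scene is assembled from parametric vessel fibers — circular arcs, straight
lines and sinusoid-perturbed lines — whose arc length, arc/chord tortuosity,
mean absolute curvature, inflection count, caliber and layout are all known
in closed form or by quadrature on the generating curve.  The scene layout
mimics a disc-centered fundus photograph:

* a bright circular field of view (FOV), optionally clipped by frame edges;
* an elliptical optic disc and a fovea point temporal to it;
* two thick arcade fibers per vessel class crossing the arcade sampling
  circle at planted angles about the disc-fovea axis;
* six radial "spoke" fibers per class through the peripapillary measurement
  annulus, carrying the planted CRE width set;
* small branching trees in the temporal periphery with planted bifurcation
  angles.

Within one vessel class fibers never overlap (so the measured skeleton
topology equals the planted topology); artery-vein crossings are allowed
and produce label-3 pixels, as in real images.  All randomness flows from a
single seed through `random_scene_config`; `generate_scene` is a pure
function of its config, so identical configs give bit-identical scenes.

Geometry uses the package-wide convention: (x=column, y=row), 0-based,
y increasing downward ("superior" structures have smaller y).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from ._geometry import arc_tortuosity, circle_through, polyline_length
from .biomarkers import FEATURE_NAMES, CREConfig, FeatureSet, cre
from .errors import ConfigInfeasible, UnknownMode
from .keypoint import Keypoint
from .preprocess import FundusBounds
from .regions import DiscGeometry
from .vesselgraph import Node, Segment, VesselGraph

__all__ = [
    "Fiber",
    "ClassSpec",
    "SceneConfig",
    "SyntheticScene",
    "random_scene_config",
    "generate_scene",
    "planted_features",
    "degrade_scene",
    "make_tree",
    "rasterize_fibers",
]


# ---------------------------------------------------------------------------
# parametric fibers


@dataclass
class Fiber:
    """One vessel fiber: a parametric curve stroked at constant caliber.

    curve kinds:
      line: p0 -> p1
      arc: circle `center`, `radius`, parameter from `a0` to `a1` (radians)
      sine: from p0 along unit `direction` for `length` px, displaced by
            amplitude * sin(2*pi*t/wavelength + phase) along the normal
    """

    kind: str  # "arcade" | "spoke" | "branch"
    vessel_class: str  # "artery" | "vein"
    caliber: float
    curve: str  # "line" | "arc" | "sine"
    p0: Optional[np.ndarray] = None
    p1: Optional[np.ndarray] = None
    center: Optional[np.ndarray] = None
    radius: float = 0.0
    a0: float = 0.0
    a1: float = 0.0
    direction: Optional[np.ndarray] = None
    amplitude: float = 0.0
    wavelength: float = 0.0
    phase: float = 0.0
    length_param: float = 0.0  # sine: extent along `direction`

    # -- sampling ----------------------------------------------------------
    def polyline(self, spacing: float = 0.5) -> np.ndarray:
        if self.curve == "line":
            L = float(np.linalg.norm(self.p1 - self.p0))
            n = max(int(np.ceil(L / spacing)) + 1, 2)
            t = np.linspace(0.0, 1.0, n)[:, None]
            return self.p0[None, :] * (1 - t) + self.p1[None, :] * t
        if self.curve == "arc":
            arc_len = abs(self.a1 - self.a0) * self.radius
            n = max(int(np.ceil(arc_len / spacing)) + 1, 2)
            t = np.linspace(self.a0, self.a1, n)
            return np.column_stack(
                [
                    self.center[0] + self.radius * np.cos(t),
                    self.center[1] + self.radius * np.sin(t),
                ]
            )
        if self.curve == "sine":
            n = max(int(np.ceil(self.length_param * 4 / spacing)) + 1, 64)
            t = np.linspace(0.0, self.length_param, n)
            d = self.direction
            nrm = np.array([-d[1], d[0]])
            disp = self.amplitude * np.sin(2 * np.pi * t / self.wavelength + self.phase)
            return (
                self.p0[None, :]
                + t[:, None] * d[None, :]
                + disp[:, None] * nrm[None, :]
            )
        raise ValueError(f"unknown curve {self.curve!r}")

    # -- analytic properties ----------------------------------------------
    def length(self) -> float:
        if self.curve == "line":
            return float(np.linalg.norm(self.p1 - self.p0))
        if self.curve == "arc":
            return abs(self.a1 - self.a0) * self.radius
        return polyline_length(self.polyline(0.05))  # quadrature

    def tortuosity(self) -> float:
        if self.curve == "line":
            return 1.0
        if self.curve == "arc":
            return arc_tortuosity(abs(self.a1 - self.a0))
        pl = self.polyline(0.05)
        return polyline_length(pl) / float(np.linalg.norm(pl[-1] - pl[0]))

    def mean_abs_curvature(self) -> float:
        """Arc-length-weighted mean |kappa| in 1/px."""
        if self.curve == "line":
            return 0.0
        if self.curve == "arc":
            return 1.0 / self.radius
        # quadrature on the analytic curvature of the displaced line
        t = np.linspace(0.0, self.length_param, 20001)
        w = 2 * np.pi / self.wavelength
        f1 = self.amplitude * w * np.cos(w * t + self.phase)
        f2 = -self.amplitude * w**2 * np.sin(w * t + self.phase)
        ds = np.sqrt(1 + f1**2)
        kappa = np.abs(f2) / ds**3
        return float(np.trapezoid(kappa * ds, t) / np.trapezoid(ds, t))

    def inflections(self) -> int:
        if self.curve != "sine":
            return 0
        # sign changes of f'' = -sin(w t + phase) on the open interval
        w = 2 * np.pi / self.wavelength
        a, b = self.phase, w * self.length_param + self.phase
        k = np.ceil(a / np.pi)
        count = 0
        while k * np.pi < b - 1e-9:
            if k * np.pi > a + 1e-9:
                count += 1
            k += 1
        return count

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        pl = self.polyline(1.0)
        return pl[0], pl[-1]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ClassSpec:
    """Planted structure of one vessel class (all px values in frame units)."""

    arcade_angles_deg: tuple[float, float] = (62.0, 62.0)  # (superior, inferior)
    arcade_shape_angle_deg: float = 62.0  # crossing angle of the unrotated shape
    arcade_calibers: tuple[float, float] = (14.0, 13.0)
    arcade_start: tuple[float, float] = (0.8, 100.0)  # (radius DD, |angle| deg)
    arcade_end: tuple[float, float] = (2.9, 26.0)
    # Spokes of the two classes interleave in the nasal band [128, 232] deg
    # with ~9 deg gaps; all spokes bend to the same normal side so the
    # neighbouring bulges track each other instead of colliding.  Three
    # spokes per class share the class's modal width, giving the pooled
    # caliber distribution a wide plateau at its median.
    spoke_angles_deg: tuple[float, ...] = (131.0, 149.0, 167.0, 185.0, 203.0, 221.0)
    spoke_widths: tuple[float, ...] = (10.0, 10.0, 6.0, 10.0, 4.0, 3.0)
    # spoke bend radii alternate between a strongly-curved and a gently-
    # curved triple; the two arcades (identical curvature, long and stably
    # measured) then sit at the central ranks of the per-class curvature
    # distribution, making the curvature median robust to per-spoke
    # measurement noise
    spoke_radii: tuple[float, ...] = (230.0, 455.0, 225.0, 470.0, 240.0, 490.0)
    spoke_span_dd: tuple[float, float] = (0.72, 1.9)
    tortuosity_mode: str = "arc"  # "arc" | "sine"
    sine_amplitude: float = 4.0
    sine_wavelength: float = 120.0
    tree_angles_deg: tuple[float, ...] = (13.0, -13.0)
    tree_root_radius_dd: float = 2.6
    bifurcations_per_tree: int = 1
    branch_angles_deg: tuple[float, ...] = (80.0, 70.0)  # one per bifurcation
    root_caliber: float = 7.0
    caliber_decay: tuple[float, float] = (0.72, 0.58)
    parent_length: float = 70.0
    daughter_length: float = 55.0


def _default_artery() -> ClassSpec:
    return ClassSpec()


def _default_vein() -> ClassSpec:
    return ClassSpec(
        arcade_angles_deg=(66.0, 66.0),
        arcade_shape_angle_deg=66.0,
        arcade_calibers=(16.0, 15.0),
        arcade_start=(0.92, 108.0),
        arcade_end=(3.1, 20.0),
        spoke_angles_deg=(140.0, 158.0, 176.0, 194.0, 212.0, 230.0),
        spoke_widths=(3.5, 11.0, 11.0, 5.0, 11.0, 7.0),
        spoke_radii=(235.0, 465.0, 228.0, 480.0, 242.0, 505.0),
        tree_angles_deg=(6.5, -6.5),
        tree_root_radius_dd=2.45,
        branch_angles_deg=(85.0, 65.0),
        root_caliber=8.0,
        caliber_decay=(0.70, 0.56),
    )


@dataclass
class SceneConfig:
    frame_size: int = 1024
    fov_center: tuple[float, float] = (512.0, 512.0)
    fov_radius: float = 504.0
    disc_center: tuple[float, float] = (328.0, 512.0)
    disc_axes: tuple[float, float] = (68.0, 63.0)  # semi-axes px
    fovea_dd: float = 2.5  # fovea distance from disc center, DD units, along +x
    artery: ClassSpec = field(default_factory=_default_artery)
    vein: ClassSpec = field(default_factory=_default_vein)
    texture_amplitude: float = 0.02
    seed: int = 0

    @property
    def dd(self) -> float:
        """Analytic disc equivalent diameter: 2*sqrt(a*b) for the ellipse."""
        return 2.0 * float(np.sqrt(self.disc_axes[0] * self.disc_axes[1]))

    @property
    def fovea(self) -> tuple[float, float]:
        return (
            self.disc_center[0] + self.fovea_dd * self.dd,
            self.disc_center[1],
        )


@dataclass
class SceneTruth:
    graphs: dict[str, VesselGraph]
    features: FeatureSet
    disc: DiscGeometry
    fibers: dict[str, list[Fiber]]
    bifurcation_angles: dict[str, list[float]]


@dataclass
class SyntheticScene:
    image: np.ndarray
    artery_mask: np.ndarray
    vein_mask: np.ndarray
    av_label_mask: np.ndarray
    disc_mask: np.ndarray
    fovea: Keypoint
    bounds_truth: FundusBounds
    truth: SceneTruth
    config: SceneConfig


# ---------------------------------------------------------------------------
# layout


def _unit(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array([np.cos(a), np.sin(a)])


def make_tree(
    root: np.ndarray,
    direction_deg: float,
    n_bifurcations: int,
    branch_angles_deg: tuple[float, ...],
    root_caliber: float,
    caliber_decay: tuple[float, float],
    parent_length: float,
    daughter_length: float,
    vessel_class: str,
) -> tuple[list[Fiber], list[float]]:
    """A branching tree of straight fibers with planted bifurcation angles.

    At each bifurcation the incoming branch splits into a continuation
    daughter (turning 0.3*a alternately left/right) and a terminal daughter
    (turning 0.7*a to the other side), so the full planted angle `a` opens
    between the two daughters while the main path stays roughly straight.
    Returns (fibers, planted angles actually used).
    """
    fibers: list[Fiber] = []
    used: list[float] = []
    pos = np.asarray(root, float)
    heading = direction_deg
    caliber = root_caliber
    length = parent_length
    side = 1.0
    for i in range(n_bifurcations):
        a = branch_angles_deg[i % len(branch_angles_deg)]
        end = pos + length * _unit(heading)
        fibers.append(
            Fiber("branch", vessel_class, caliber, "line", p0=pos.copy(), p1=end)
        )
        cont_turn = side * 0.3 * a
        term_turn = -side * 0.7 * a
        term_len = daughter_length * (0.92**i)
        term_cal = max(caliber * caliber_decay[1], 1.6)
        term_end = end + term_len * _unit(heading + term_turn)
        fibers.append(
            Fiber(
                "branch",
                vessel_class,
                term_cal,
                "line",
                p0=end.copy(),
                p1=term_end,
            )
        )
        used.append(a)
        pos = end
        heading = heading + cont_turn
        # rasterization floor: sub-1.6 px strokes thin out and disconnect
        caliber = max(caliber * caliber_decay[0], 1.8)
        length = daughter_length * (0.92**i)
        side = -side
    # final continuation daughter closes the last bifurcation
    end = pos + length * _unit(heading)
    fibers.append(
        Fiber("branch", vessel_class, caliber, "line", p0=pos.copy(), p1=end)
    )
    return fibers, used


def _class_fibers(cfg: SceneConfig, spec: ClassSpec, vessel_class: str):
    """All fibers of one class, plus planted bifurcation angles."""
    c = np.asarray(cfg.disc_center, float)
    dd = cfg.dd
    fibers: list[Fiber] = []

    # Arcades: a fixed arc *shape* (circle through start / crossing-at-shape-
    # angle / end control points) rotated rigidly about the disc center so
    # the planted crossing angle is hit exactly.  Rigid rotation keeps the
    # arc radius — hence the arcade's planted curvature — independent of the
    # randomized crossing angle.
    for which, sign in ((0, -1.0), (1, 1.0)):
        theta = spec.arcade_angles_deg[which]
        delta = sign * (theta - spec.arcade_shape_angle_deg)
        r0, a0 = spec.arcade_start
        r1, a1 = spec.arcade_end
        p_start = c + r0 * dd * _unit(sign * a0 + delta)
        p_cross = c + 1.5 * dd * _unit(sign * theta)
        p_end = c + r1 * dd * _unit(sign * a1 + delta)
        center, radius = circle_through(p_start, p_cross, p_end)
        angs = [
            np.arctan2(p[1] - center[1], p[0] - center[0])
            for p in (p_start, p_cross, p_end)
        ]
        # unwrap so the parameter passes through the crossing point
        a_s, a_m, a_e = np.unwrap(angs)
        fibers.append(
            Fiber(
                "arcade",
                vessel_class,
                spec.arcade_calibers[which],
                "arc",
                center=center,
                radius=radius,
                a0=a_s,
                a1=a_e,
            )
        )

    # spokes through the measurement annulus
    lo, hi = spec.spoke_span_dd
    for ang, wdt, rad in zip(
        spec.spoke_angles_deg, spec.spoke_widths, spec.spoke_radii
    ):
        p0 = c + lo * dd * _unit(ang)
        p1 = c + hi * dd * _unit(ang)
        if spec.tortuosity_mode == "sine":
            d = (p1 - p0) / np.linalg.norm(p1 - p0)
            fibers.append(
                Fiber(
                    "spoke",
                    vessel_class,
                    wdt,
                    "sine",
                    p0=p0,
                    direction=d,
                    amplitude=spec.sine_amplitude,
                    wavelength=spec.sine_wavelength,
                    phase=0.0,
                    length_param=float(np.linalg.norm(p1 - p0)),
                )
            )
        elif rad and np.isfinite(rad):
            # constant-curvature spoke: arc through p0, p1 with radius |rad|,
            # bulging to the side given by sign(rad)
            mid = (p0 + p1) / 2.0
            chord = np.linalg.norm(p1 - p0)
            R = max(abs(rad), chord / 2.0 + 1e-6)
            h = np.sqrt(R**2 - (chord / 2.0) ** 2)
            d = (p1 - p0) / chord
            nrm = np.array([-d[1], d[0]]) * np.sign(rad)
            center = mid + h * nrm
            aa0 = np.arctan2(p0[1] - center[1], p0[0] - center[0])
            aa1 = np.arctan2(p1[1] - center[1], p1[0] - center[0])
            aa0, aa1 = np.unwrap([aa0, aa1])
            fibers.append(
                Fiber(
                    "spoke",
                    vessel_class,
                    wdt,
                    "arc",
                    center=center,
                    radius=R,
                    a0=aa0,
                    a1=aa1,
                )
            )
        else:
            fibers.append(
                Fiber("spoke", vessel_class, wdt, "line", p0=p0, p1=p1)
            )

    # temporal trees
    bif_angles: list[float] = []
    n_angles_per_tree = spec.bifurcations_per_tree
    for ti, tang in enumerate(spec.tree_angles_deg):
        root = c + spec.tree_root_radius_dd * dd * _unit(tang)
        angles = tuple(
            spec.branch_angles_deg[
                (ti * n_angles_per_tree + k) % len(spec.branch_angles_deg)
            ]
            for k in range(n_angles_per_tree)
        )
        tf, used = make_tree(
            root,
            tang,
            spec.bifurcations_per_tree,
            angles,
            spec.root_caliber,
            spec.caliber_decay,
            spec.parent_length,
            spec.daughter_length,
            vessel_class,
        )
        fibers.extend(tf)
        bif_angles.extend(used)

    return fibers, bif_angles


def _validate_layout(cfg: SceneConfig, fibers: list[Fiber]) -> None:
    cx, cy = cfg.fov_center
    S = cfg.frame_size
    fx, fy = cfg.fovea
    if np.hypot(fx - cx, fy - cy) >= cfg.fov_radius:
        raise ConfigInfeasible("fovea outside the field of view")
    if not (0 <= fx < S and 0 <= fy < S):
        raise ConfigInfeasible("fovea outside the frame")
    for f in fibers:
        pl = f.polyline(4.0)
        rr = np.hypot(pl[:, 0] - cx, pl[:, 1] - cy) + f.caliber / 2.0
        if rr.max() >= cfg.fov_radius - 2:
            raise ConfigInfeasible(
                f"{f.kind} fiber extends outside the field of view"
            )
        if (
            pl.min() - f.caliber / 2.0 < 0
            or pl.max() + f.caliber / 2.0 >= cfg.frame_size
        ):
            raise ConfigInfeasible(f"{f.kind} fiber extends outside the frame")


def _check_class_clearance(fibers: list[Fiber], margin: float = 3.0) -> None:
    """Enforce the within-class disjointness invariant.

    Any two fibers of the same class that do not share a tree junction must
    keep their stroked masks separated; a violation would merge planted
    structures in the rendered skeleton and silently corrupt the ground
    truth, so it is rejected at construction time.
    """
    polys = [f.polyline(1.5) for f in fibers]
    trees = [cKDTree(p) for p in polys]
    for i in range(len(fibers)):
        for j in range(i + 1, len(fibers)):
            fi, fj = fibers[i], fibers[j]
            pi, pj = polys[i], polys[j]
            shared = min(
                float(np.linalg.norm(a - b))
                for a in (pi[0], pi[-1])
                for b in (pj[0], pj[-1])
            ) < 1.0
            if shared:
                continue
            d, _ = trees[j].query(pi, k=1)
            if d.min() < (fi.caliber + fj.caliber) / 2.0 + margin:
                raise ConfigInfeasible(
                    f"{fi.vessel_class} {fi.kind}#{i} and {fj.kind}#{j} "
                    f"strokes come within {d.min():.1f} px"
                )


# ---------------------------------------------------------------------------
# rasterization


def _joined_ends(fibers: list[Fiber]) -> list[tuple[bool, bool]]:
    """Per fiber: whether its (start, end) coincides with another fiber's
    endpoint (a tree junction) rather than being a free vessel tip."""
    endpoints = []
    for f in fibers:
        pl1 = f.polyline(4.0)
        endpoints.append((pl1[0], pl1[-1]))
    out = []
    for fi, (p0, p1) in enumerate(endpoints):
        flags = []
        for p_end in (p0, p1):
            flags.append(
                any(
                    min(
                        float(np.linalg.norm(p_end - q0)),
                        float(np.linalg.norm(p_end - q1)),
                    )
                    < 1.0
                    for fj, (q0, q1) in enumerate(endpoints)
                    if fj != fi
                )
            )
        out.append((flags[0], flags[1]))
    return out


def rasterize_fibers(
    fibers: list[Fiber], shape: tuple[int, int]
) -> np.ndarray:
    """Anti-aliased coverage in [0, 1] of a set of stroked fibers.

    Coverage per pixel is clip(h + 1/2 - d, 0, 1) with d the distance from
    the pixel center to the fiber centerline and h the local half-width;
    thresholding at 0.5 gives a mask whose width matches the planted
    caliber within a pixel.  The half-width tapers linearly over the last
    caliber of arc length at each free end (w/2 down to w/6), the way real
    vessel ends and cut-offs thin out; blunt caps would otherwise leave
    thinning artifacts ("fishtails") in downstream skeletons at any scale.
    Ends that join another fiber of the set (tree junctions) are not
    tapered.
    """
    h, w = shape
    joined_ends = _joined_ends(fibers)
    cov = np.zeros((h, w), dtype=float)
    for fi, f in enumerate(fibers):
        pl = f.polyline(0.35)
        seg = np.linalg.norm(np.diff(pl, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        halfw = np.full(len(pl), f.caliber / 2.0)
        for at_start in (True, False):
            if joined_ends[fi][0 if at_start else 1]:
                continue
            d_tip = s if at_start else s[-1] - s
            frac = np.clip(1.0 / 3.0 + (2.0 / 3.0) * d_tip / max(f.caliber, 1e-6), None, 1.0)
            halfw = np.minimum(halfw, (f.caliber / 2.0) * frac)
        pad = f.caliber / 2.0 + 2.0
        x0 = max(int(np.floor(pl[:, 0].min() - pad)), 0)
        x1 = min(int(np.ceil(pl[:, 0].max() + pad)), w - 1)
        y0 = max(int(np.floor(pl[:, 1].min() - pad)), 0)
        y1 = min(int(np.ceil(pl[:, 1].max() + pad)), h - 1)
        if x1 < x0 or y1 < y0:
            continue
        yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        tree = cKDTree(pl)
        d, idx = tree.query(pts, k=1)
        local = np.clip(halfw[idx] + 0.5 - d, 0.0, 1.0).reshape(yy.shape)
        region = cov[y0 : y1 + 1, x0 : x1 + 1]
        np.maximum(region, local, out=region)
    return cov


def stroked_area(f: Fiber, tapered_ends: tuple[bool, bool] = (True, True)) -> float:
    """Analytic area of one rendered fiber, matching `rasterize_fibers`.

    A straight stretch contributes length x caliber; each tapered free end
    replaces a w/2 half-width by the linear taper (losing w^2/6) and ends
    in a half-disc of radius w/6; an untapered (joined) end keeps the full
    half-disc cap of radius w/2.
    """
    wdt = f.caliber
    area = f.length() * wdt
    for tapered in tapered_ends:
        if tapered:
            # linear taper w -> w/3 over one caliber: integral deficit w^2/3
            area -= wdt**2 / 3.0
            area += np.pi * (wdt / 6.0) ** 2 / 2.0
        else:
            area += np.pi * (wdt / 2.0) ** 2 / 2.0
    return float(area)


def _truth_graph(fibers: list[Fiber], vessel_class: str, shape) -> VesselGraph:
    """Planted centerline graph: fiber endpoints become nodes; tree fibers
    sharing endpoints share nodes."""
    g = VesselGraph(vessel_class=vessel_class, frame_shape=tuple(shape))
    pos_to_node: dict[tuple[int, int], int] = {}

    def node_at(p: np.ndarray) -> int:
        key = (int(round(p[0] * 4)), int(round(p[1] * 4)))
        if key not in pos_to_node:
            nid = len(g.nodes)
            g.nodes[nid] = Node(nid, np.asarray(p, float), "endpoint")
            pos_to_node[key] = nid
        return pos_to_node[key]

    for f in fibers:
        pl = f.polyline(1.0)
        u, v = node_at(pl[0]), node_at(pl[-1])
        g.segments.append(
            Segment(
                points=pl,
                u=u,
                v=v,
                calibers=np.full(len(pl), f.caliber),
            )
        )
    g.recompute_degrees()
    for n in g.nodes.values():
        n.kind = "branchpoint" if n.degree >= 3 else "endpoint"
    return g


# ---------------------------------------------------------------------------
# planted feature values


def planted_features(config: SceneConfig) -> FeatureSet:
    """Analytic Table-of-24 feature values implied by the scene config.

    Values are derived from the generating curves (quadrature where no
    closed form exists), never from rasters; the chain-recovery tests
    compare these against what the measurement pipeline reads back from the
    rendered masks.
    """
    fs = FeatureSet()
    dd = config.dd
    disc_r = dd / 2.0
    fov_area = _fov_area(config) - np.pi * disc_r**2
    for suffix, spec, kind in (
        ("A", config.artery, "artery"),
        ("V", config.vein, "vein"),
    ):
        fibers, bif_angles = _class_fibers(config, spec, kind)
        segs = [f for f in fibers if f.length() >= 20.0]
        torts = np.array([f.tortuosity() for f in segs])
        lens = np.array([f.length() for f in segs])
        # curvature/inflection aggregate only over segments long enough for
        # an interior estimate (mirrors the measurement pipeline's rule)
        long_segs = [f for f in segs if f.length() >= 80.0]
        curvs = np.array([f.mean_abs_curvature() * 1e3 for f in long_segs])
        inflections = np.array([f.inflections() for f in long_segs])
        fs[f"tortuosity_med_{suffix}"] = float(np.median(torts))
        fs[f"tortuosity_lw_{suffix}"] = float((torts * lens).sum() / lens.sum())
        fs[f"curvature_med_{suffix}"] = float(np.median(curvs))
        fs[f"inflection_count_med_{suffix}"] = float(np.median(inflections))

        # pooled caliber statistics, length-weighted, with one caliber
        # trimmed at each fiber tip (the measurement excludes tip points)
        cals = np.array([f.caliber for f in fibers])
        eff = np.maximum(
            np.array([f.length() for f in fibers]) - 2 * cals, 0.0
        )
        order = np.argsort(cals)
        cum = np.cumsum(eff[order])
        fs[f"caliber_med_{suffix}"] = float(
            cals[order][np.searchsorted(cum, cum[-1] / 2.0)]
        )
        mean_c = float((cals * eff).sum() / eff.sum())
        fs[f"caliber_std_{suffix}"] = float(
            np.sqrt((eff * (cals - mean_c) ** 2).sum() / eff.sum())
        )

        # density: analytic stroked area over the FOV (taper-aware)
        area = float(
            sum(
                stroked_area(f, (not js, not je))
                for f, (js, je) in zip(fibers, _joined_ends(fibers))
            )
        )
        fs[f"vascular_density_{suffix}"] = 100.0 * area / fov_area

        # CRE from the planted widths of fibers crossing the annulus
        zone_widths = sorted(
            (
                f.caliber
                for f in fibers
                if f.kind in ("arcade", "spoke")
            ),
            reverse=True,
        )[:6]
        fs[f"cre_{suffix}"] = cre(zone_widths, kind, CREConfig())

        fs[f"temporal_angle_{suffix}"] = float(
            spec.arcade_angles_deg[0] + spec.arcade_angles_deg[1]
        )
        fs[f"n_bifurcations_{suffix}"] = float(len(bif_angles))
        if bif_angles:
            fs[f"bif_angle_mean_{suffix}"] = float(np.mean(bif_angles))
            fs[f"bif_angle_med_{suffix}"] = float(np.median(bif_angles))
        else:
            fs.mark_missing(f"bif_angle_mean_{suffix}", "no planted bifurcations")
            fs.mark_missing(f"bif_angle_med_{suffix}", "no planted bifurcations")
    return fs


def _fov_area(config: SceneConfig) -> float:
    """Area of the FOV circle intersected with the frame (analytic-ish:
    pixel-count on a fine implicit grid is avoided; circle-rectangle overlap
    is computed by 1D integration, accurate to ~1e-3 relative)."""
    cx, cy = config.fov_center
    R = config.fov_radius
    S = config.frame_size
    xs = np.linspace(max(cx - R, 0.0), min(cx + R, S - 1.0), 4001)
    half = np.sqrt(np.clip(R**2 - (xs - cx) ** 2, 0.0, None))
    y_lo = np.clip(cy - half, -0.5, S - 0.5)
    y_hi = np.clip(cy + half, -0.5, S - 0.5)
    return float(np.trapezoid(y_hi - y_lo, xs))


# ---------------------------------------------------------------------------
# scene generation


def _fov_bounds(config: SceneConfig) -> FundusBounds:
    cx, cy = config.fov_center
    R = config.fov_radius
    S = config.frame_size
    # a line is planted only when the circle overruns the frame by more
    # than a pixel: sub-pixel truncations leave no flat chord to detect
    return FundusBounds(
        center_x=cx,
        center_y=cy,
        radius=R,
        top=0.0 if cy - R < -1.0 else None,
        bottom=float(S - 1) if cy + R > S else None,
        left=0.0 if cx - R < -1.0 else None,
        right=float(S - 1) if cx + R > S else None,
    )


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render a scene and package it with its full analytic ground truth."""
    S = config.frame_size
    shape = (S, S)
    artery_fibers, artery_bifs = _class_fibers(config, config.artery, "artery")
    vein_fibers, vein_bifs = _class_fibers(config, config.vein, "vein")
    _validate_layout(config, artery_fibers + vein_fibers)
    _check_class_clearance(artery_fibers)
    _check_class_clearance(vein_fibers)

    bounds = _fov_bounds(config)
    fov_mask = bounds.mask(shape)

    cov_a = rasterize_fibers(artery_fibers, shape)
    cov_v = rasterize_fibers(vein_fibers, shape)
    artery_mask = (cov_a >= 0.5).astype(np.uint8)
    vein_mask = (cov_v >= 0.5).astype(np.uint8)
    av = np.zeros(shape, dtype=np.uint8)
    av[artery_mask == 1] = 1
    av[vein_mask == 1] = 2
    av[(artery_mask == 1) & (vein_mask == 1)] = 3

    # disc ellipse
    yy, xx = np.mgrid[0:S, 0:S]
    dcx, dcy = config.disc_center
    a, b = config.disc_axes
    disc_field = ((xx - dcx) / a) ** 2 + ((yy - dcy) / b) ** 2
    disc_mask = (disc_field <= 1.0).astype(np.uint8)

    # image: warm fundus background with radial shading and smooth texture
    rng = np.random.default_rng(config.seed)
    rr2 = ((xx - config.fov_center[0]) ** 2 + (yy - config.fov_center[1]) ** 2) / (
        config.fov_radius**2
    )
    shade = 1.0 - 0.25 * np.clip(rr2, 0.0, 1.0)
    texture = ndi.gaussian_filter(rng.standard_normal(shape), 12.0)
    tmax = np.abs(texture).max()
    if tmax > 0:
        texture = texture / tmax * config.texture_amplitude
    base = np.stack(
        [0.82 * shade + texture, 0.46 * shade + texture, 0.24 * shade + texture],
        axis=-1,
    )
    disc_soft = np.clip(1.2 - disc_field, 0.0, 1.0)
    disc_color = np.array([0.96, 0.86, 0.62])
    img = base * (1 - disc_soft[..., None]) + disc_color * disc_soft[..., None]
    vessel_att = (1 - 0.45 * cov_a) * (1 - 0.62 * cov_v)
    img = img * vessel_att[..., None]
    img = np.clip(img, 0.0, 1.0)
    img[~fov_mask] = 0.0

    dd = config.dd
    truth = SceneTruth(
        graphs={
            "artery": _truth_graph(artery_fibers, "artery", shape),
            "vein": _truth_graph(vein_fibers, "vein", shape),
        },
        features=planted_features(config),
        disc=DiscGeometry(dcx, dcy, dd),
        fibers={"artery": artery_fibers, "vein": vein_fibers},
        bifurcation_angles={"artery": artery_bifs, "vein": vein_bifs},
    )
    fovea = Keypoint(x=config.fovea[0], y=config.fovea[1], frame=shape)
    return SyntheticScene(
        image=img,
        artery_mask=artery_mask,
        vein_mask=vein_mask,
        av_label_mask=av,
        disc_mask=disc_mask,
        fovea=fovea,
        bounds_truth=bounds,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# randomized study conditions


def random_scene_config(
    seed: int,
    frame_size: int = 1024,
    edge_clip: bool = False,
) -> SceneConfig:
    """Draw a randomized but geometrically safe scene configuration.

    All stochastic choices are drawn from one stream in fixed order (FOV,
    disc, fovea, arcade angles/calibers, spoke jitters, tree angles), so a
    given seed always produces the same config.  Candidate layouts that
    violate the generator's feasibility invariants (fibers inside the FOV,
    within-class stroke clearance) are rejected and redrawn from the same
    stream, which keeps the procedure deterministic per seed.  `edge_clip`
    draws an FOV circle that overruns the top and bottom frame edges,
    planting flat clipping lines there.
    """
    rng = np.random.default_rng(seed)
    for _ in range(64):
        cfg = _draw_scene_config(rng, frame_size, edge_clip)
        try:
            a, _ = _class_fibers(cfg, cfg.artery, "artery")
            v, _ = _class_fibers(cfg, cfg.vein, "vein")
            _validate_layout(cfg, a + v)
            _check_class_clearance(a)
            _check_class_clearance(v)
        except ConfigInfeasible:
            continue
        return cfg
    raise ConfigInfeasible(
        f"no feasible layout found for seed {seed} after 64 attempts"
    )


def _draw_scene_config(
    rng: np.random.Generator, frame_size: int, edge_clip: bool
) -> SceneConfig:
    s = frame_size / 1024.0
    if edge_clip:
        fov_radius = frame_size * rng.uniform(0.52, 0.58)
    else:
        fov_radius = frame_size * rng.uniform(0.46, 0.485)
    fov_center = (
        frame_size / 2.0 + rng.uniform(-0.01, 0.01) * frame_size,
        frame_size / 2.0 + rng.uniform(-0.01, 0.01) * frame_size,
    )
    disc_center = (
        frame_size * rng.uniform(0.32, 0.34),
        frame_size * rng.uniform(0.48, 0.52),
    )
    disc_a = frame_size * rng.uniform(0.060, 0.068)
    disc_b = disc_a * rng.uniform(0.88, 0.98)

    def jitter(vals, lo, hi):
        return tuple(float(v) * rng.uniform(lo, hi) for v in vals)

    def cls(base: ClassSpec, theta_lo: float, theta_hi: float) -> ClassSpec:
        width_factor = float(rng.uniform(0.92, 1.08))
        return replace(
            base,
            # the lower bound keeps the rotated arcade tail clear of the
            # temporal trees of the same class
            arcade_angles_deg=(
                float(rng.uniform(theta_lo, theta_hi)),
                float(rng.uniform(theta_lo, theta_hi)),
            ),
            arcade_calibers=jitter(base.arcade_calibers, 0.92, 1.08),
            spoke_angles_deg=tuple(
                float(a + rng.uniform(-2.0, 2.0)) for a in base.spoke_angles_deg
            ),
            # one shared width factor per class keeps the planted caliber
            # plateau intact while still varying scenes
            spoke_widths=tuple(
                float(w) * width_factor for w in base.spoke_widths
            ),
            spoke_radii=tuple(
                float(
                    rng.uniform(215, 245) * s
                    if i % 2 == 0
                    else rng.uniform(450, 520) * s
                )
                for i in range(len(base.spoke_radii))
            ),
            branch_angles_deg=tuple(
                float(rng.uniform(52, 108)) for _ in base.branch_angles_deg
            ),
            tree_angles_deg=tuple(
                float(a + rng.uniform(-1.5, 1.5)) for a in base.tree_angles_deg
            ),
        )

    def scale(spec: ClassSpec) -> ClassSpec:
        return replace(
            spec,
            arcade_calibers=tuple(c * s for c in spec.arcade_calibers),
            spoke_widths=tuple(max(w * s, 1.5) for w in spec.spoke_widths),
            root_caliber=spec.root_caliber * s,
            parent_length=spec.parent_length * s,
            daughter_length=spec.daughter_length * s,
        )

    return SceneConfig(
        frame_size=frame_size,
        fov_center=fov_center,
        fov_radius=fov_radius,
        disc_center=disc_center,
        disc_axes=(disc_a, disc_b),
        fovea_dd=float(rng.uniform(2.35, 2.6)),
        artery=scale(cls(_default_artery(), 55.0, 68.0)),
        vein=scale(cls(_default_vein(), 59.0, 68.0)),
        texture_amplitude=0.02,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# degradations


def degrade_scene(
    scene: SyntheticScene, mode: str, magnitude: float, seed: int = 0
) -> SyntheticScene:
    """Image-quality degradations with ground truth left untouched.

    blur: Gaussian blur of the image, sigma = 8 * magnitude px.
    vignette: radial intensity falloff by (1 - magnitude * (r/R)^2).
    dropout: random square patches removed from the *returned mask variants*
             (never from `truth`), emulating broken segmentations.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    img = scene.image.copy()
    artery, vein, av = (
        scene.artery_mask.copy(),
        scene.vein_mask.copy(),
        scene.av_label_mask.copy(),
    )
    if mode == "blur":
        if magnitude > 0:
            sigma = 8.0 * magnitude
            img = np.stack(
                [ndi.gaussian_filter(img[..., c], sigma) for c in range(3)], axis=-1
            )
            img[~scene.bounds_truth.mask(img.shape[:2])] = 0.0
    elif mode == "vignette":
        h, w = img.shape[:2]
        yy, xx = np.mgrid[0:h, 0:w]
        rr2 = (
            (xx - scene.bounds_truth.center_x) ** 2
            + (yy - scene.bounds_truth.center_y) ** 2
        ) / scene.bounds_truth.radius**2
        img = img * (1.0 - magnitude * np.clip(rr2, 0, 1))[..., None]
    elif mode == "dropout":
        rng = np.random.default_rng(seed)
        h, w = artery.shape
        n_patches = int(round(20 * magnitude))
        for _ in range(n_patches):
            size = int(rng.integers(8, 24))
            y = int(rng.integers(0, h - size))
            x = int(rng.integers(0, w - size))
            artery[y : y + size, x : x + size] = 0
            vein[y : y + size, x : x + size] = 0
            av[y : y + size, x : x + size] = 0
    else:
        raise UnknownMode(f"unknown degradation mode {mode!r}")
    return SyntheticScene(
        image=img,
        artery_mask=artery,
        vein_mask=vein,
        av_label_mask=av,
        disc_mask=scene.disc_mask,
        fovea=scene.fovea,
        bounds_truth=scene.bounds_truth,
        truth=scene.truth,
        config=scene.config,
    )
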