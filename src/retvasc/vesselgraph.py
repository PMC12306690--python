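"""Vessel masks → centerline graphs with per-point calibers.

The artery/vein label encoding follows the 4-level convention: background
(0), arteries (1), veins (2), crossings belonging to both (3).  Binary
vessel masks are thinned to 1-px-wide skeletons, which are decomposed into
a graph of endpoint/branchpoint nodes joined by centerline segments; the
Euclidean distance transform of the source mask provides a caliber estimate
at every centerline point (caliber = 2 x distance to the nearest background
pixel).  8-connectivity is used throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import remove_small_holes
from skimage.morphology import skeletonize as _skimage_skeletonize

from ._geometry import polyline_length, cumulative_arclength, smooth_polyline
from .errors import FrameMismatch, InvalidLabel

__all__ = [
    "Node",
    "Segment",
    "VesselGraph",
    "split_av_labels",
    "skeletonize",
    "build_graph",
    "estimate_calibers",
    "prune_graph",
    "mask_to_graph",
]

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class Node:
    id: int
    position: np.ndarray  # (x, y)
    kind: str  # "endpoint" | "branchpoint"
    degree: int = 0


@dataclass
class Segment:
    points: np.ndarray  # (n, 2) float, ordered, (x, y)
    u: int  # node id at points[0]
    v: int  # node id at points[-1]
    calibers: np.ndarray | None = None  # (n,) px, set by estimate_calibers
    tip: np.ndarray | None = None  # (n,) bool: within one caliber of a tip
    closed: bool = False

    @property
    def length(self) -> float:
        return polyline_length(self.points)

    def interior_calibers(self) -> np.ndarray:
        """Calibers excluding points flagged as segment tips."""
        if self.calibers is None:
            raise ValueError("calibers not estimated")
        if self.tip is None:
            return self.calibers
        return self.calibers[~self.tip]


@dataclass
class VesselGraph:
    nodes: dict[int, Node] = field(default_factory=dict)
    segments: list[Segment] = field(default_factory=list)
    vessel_class: str = "vessel"  # "artery" | "vein" | "vessel"
    frame_shape: tuple[int, int] = (0, 0)

    @property
    def n_branchpoints(self) -> int:
        return sum(1 for n in self.nodes.values() if n.kind == "branchpoint")

    def recompute_degrees(self) -> None:
        for n in self.nodes.values():
            n.degree = 0
        for s in self.segments:
            if s.closed:
                continue
            self.nodes[s.u].degree += 1
            self.nodes[s.v].degree += 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "vessel_class": self.vessel_class,
                "frame_shape": list(self.frame_shape),
                "nodes": [
                    {
                        "id": n.id,
                        "position": [float(n.position[0]), float(n.position[1])],
                        "kind": n.kind,
                        "degree": n.degree,
                    }
                    for n in self.nodes.values()
                ],
                "segments": [
                    {
                        "u": s.u,
                        "v": s.v,
                        "closed": s.closed,
                        "points": np.asarray(s.points).tolist(),
                        "calibers": None
                        if s.calibers is None
                        else np.asarray(s.calibers).tolist(),
                    }
                    for s in self.segments
                ],
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "VesselGraph":
        d = json.loads(s)
        g = cls(
            vessel_class=d["vessel_class"], frame_shape=tuple(d["frame_shape"])
        )
        for nd in d["nodes"]:
            g.nodes[nd["id"]] = Node(
                nd["id"], np.array(nd["position"], float), nd["kind"], nd["degree"]
            )
        for sd in d["segments"]:
            g.segments.append(
                Segment(
                    points=np.array(sd["points"], float),
                    u=sd["u"],
                    v=sd["v"],
                    closed=sd["closed"],
                    calibers=None
                    if sd["calibers"] is None
                    else np.array(sd["calibers"], float),
                )
            )
        return g


# ---------------------------------------------------------------------------


def split_av_labels(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """4-level A/V labels → (artery, vein) binary masks.

    Crossings (label 3) belong to both classes, mirroring the merge applied
    when artery and vein masks are recovered from a crossing-aware output.
    """
    m = np.asarray(mask)
    bad = np.setdiff1d(np.unique(m), [0, 1, 2, 3])
    if bad.size:
        raise InvalidLabel(f"labels outside {{0,1,2,3}}: {bad.tolist()}")
    artery = ((m == 1) | (m == 3)).astype(np.uint8)
    vein = ((m == 2) | (m == 3)).astype(np.uint8)
    return artery, vein


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to a 1-px, 8-connected skeleton.

    Holes of fewer than 64 px are filled first: at vessel scale they are
    aliasing artifacts, and topology-preserving thinning would otherwise
    turn each one into a tiny skeleton ring.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return np.zeros_like(m, dtype=np.uint8)
    m = remove_small_holes(m, max_size=64)
    return _skimage_skeletonize(m).astype(np.uint8)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    return ndi.convolve(skel.astype(int), k, mode="constant")


def build_graph(skeleton: np.ndarray, vessel_class: str = "vessel") -> VesselGraph:
    """Decompose a 1-px skeleton into nodes and maximal centerline segments.

    Branchpoints are skeleton pixels with >= 3 skeleton neighbors; adjacent
    branch pixels are clustered (8-connected) into a single node placed at
    their centroid.  Endpoints are pixels with exactly one neighbor.
    Segments are maximal chains between node pixels, with the owning node's
    position prepended/appended so segment endpoints coincide with node
    positions.  Cycles without any node pixel are flagged closed.
    """
    skel = np.asarray(skeleton).astype(bool)
    g = VesselGraph(vessel_class=vessel_class, frame_shape=skel.shape)
    if not skel.any():
        return g
    nbrs = _neighbor_counts(skel)
    branch_px = skel & (nbrs >= 3)
    end_px = skel & (nbrs == 1)

    # node id per skeleton pixel (-1 = not a node pixel)
    node_of_px = np.full(skel.shape, -1, dtype=int)
    next_id = 0
    clusters, n_clusters = ndi.label(branch_px, structure=np.ones((3, 3)))
    for lab in range(1, n_clusters + 1):
        ys, xs = np.nonzero(clusters == lab)
        pos = np.array([xs.mean(), ys.mean()])
        g.nodes[next_id] = Node(next_id, pos, "branchpoint")
        node_of_px[ys, xs] = next_id
        next_id += 1
    eys, exs = np.nonzero(end_px & (node_of_px < 0))
    for y, x in zip(eys, exs):
        g.nodes[next_id] = Node(next_id, np.array([float(x), float(y)]), "endpoint")
        node_of_px[y, x] = next_id
        next_id += 1

    h, w = skel.shape
    visited = np.zeros_like(skel, dtype=bool)

    def neighbors(y, x):
        for dy, dx in _OFFSETS:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and skel[ny, nx]:
                yield ny, nx

    def node_pos(nid):
        return g.nodes[nid].position.copy()

    # trace chains starting at node pixels
    node_ys, node_xs = np.nonzero(node_of_px >= 0)
    for y0, x0 in zip(node_ys, node_xs):
        u = node_of_px[y0, x0]
        for y1, x1 in neighbors(y0, x0):
            if node_of_px[y1, x1] >= 0 or visited[y1, x1]:
                continue
            chain = [(x1, y1)]
            visited[y1, x1] = True
            py, px_, cy, cx_ = y0, x0, y1, x1
            end_node = None
            while True:
                nxt = None
                for ny, nx in neighbors(cy, cx_):
                    if (ny, nx) == (py, px_):
                        continue
                    if node_of_px[ny, nx] >= 0:
                        end_node = node_of_px[ny, nx]
                        nxt = None
                        break
                    if not visited[ny, nx]:
                        nxt = (ny, nx)
                if end_node is not None or nxt is None:
                    break
                py, px_, (cy, cx_) = cy, cx_, nxt
                visited[cy, cx_] = True
                chain.append((cx_, cy))
            if end_node is None:
                # dangling chain whose tip had its neighbor consumed; treat the
                # last pixel as an endpoint node
                lx, ly = chain[-1]
                nid = len(g.nodes)
                g.nodes[nid] = Node(nid, np.array([float(lx), float(ly)]), "endpoint")
                node_of_px[ly, lx] = nid
                end_node = nid
                chain = chain[:-1]
            pts = [node_pos(u)] + [np.array(p, float) for p in chain] + [node_pos(end_node)]
            g.segments.append(Segment(points=np.array(pts), u=u, v=end_node))

    # direct adjacency between pixels of different nodes (no chain between)
    seen_pairs = {(min(s.u, s.v), max(s.u, s.v), len(s.points)) for s in g.segments}
    for y0, x0 in zip(node_ys, node_xs):
        u = node_of_px[y0, x0]
        for y1, x1 in neighbors(y0, x0):
            v = node_of_px[y1, x1]
            if v < 0 or v == u:
                continue
            key = (min(u, v), max(u, v), 2)
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            g.segments.append(
                Segment(points=np.array([node_pos(u), node_pos(v)]), u=u, v=v)
            )

    # leftover unvisited chain pixels form closed loops
    rem = skel & ~visited & (node_of_px < 0)
    rys, rxs = np.nonzero(rem)
    for y0, x0 in zip(rys, rxs):
        if visited[y0, x0]:
            continue
        loop = [(x0, y0)]
        visited[y0, x0] = True
        py, px_, cy, cx_ = -1, -1, y0, x0
        while True:
            nxt = None
            for ny, nx in neighbors(cy, cx_):
                if (ny, nx) != (py, px_) and not visited[ny, nx] and node_of_px[ny, nx] < 0:
                    nxt = (ny, nx)
                    break
            if nxt is None:
                break
            py, px_, (cy, cx_) = cy, cx_, nxt
            visited[cy, cx_] = True
            loop.append((cx_, cy))
        nid = len(g.nodes)
        g.nodes[nid] = Node(nid, np.array(loop[0], float), "branchpoint")
        pts = np.array([np.array(p, float) for p in loop] + [np.array(loop[0], float)])
        g.segments.append(Segment(points=pts, u=nid, v=nid, closed=True))

    g.recompute_degrees()
    return g


def _perpendicular_widths(
    mask_float: np.ndarray,
    centerline: np.ndarray,
    edt_calibers: np.ndarray,
    step: float = 0.25,
) -> np.ndarray:
    """Sub-pixel edge-to-edge widths along perpendicular profiles.

    The bilinearly interpolated binary mask is sampled on both sides of the
    (smoothed) centerline along the local normal; the width is the distance
    between the two 0.5-level crossings, located by linear interpolation.
    Unlike the raw distance transform this read-out does not depend on
    where the mask boundary sits relative to pixel centers, so widths stay
    consistent across resampling.  Points whose profile has no crossing
    within the search radius return NaN.
    """
    n = len(centerline)
    if n < 2:
        return np.full(n, np.nan)
    d = np.gradient(centerline, axis=0)
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    d = d / norms
    normal = np.column_stack([-d[:, 1], d[:, 0]])
    half_search = float(np.nanmax(edt_calibers)) / 2.0 + 3.0 if len(edt_calibers) else 5.0
    ts = np.arange(0.0, half_search + step, step)
    widths = np.full(n, np.nan)
    half = {}
    for sign in (1.0, -1.0):
        # samples: (n points) x (len(ts) offsets)
        px = centerline[:, 0:1] + sign * ts[None, :] * normal[:, 0:1]
        py = centerline[:, 1:2] + sign * ts[None, :] * normal[:, 1:2]
        vals = ndi.map_coordinates(
            mask_float, [py.ravel(), px.ravel()], order=1, mode="constant"
        ).reshape(n, len(ts))
        inside = vals >= 0.5
        # first offset index where the profile drops below 0.5
        drop = np.argmin(inside, axis=1)
        has_drop = ~inside[np.arange(n), drop]
        ok = has_drop & (drop > 0)
        t_cross = np.full(n, np.nan)
        k = drop[ok]
        v0 = vals[ok, k - 1]
        v1 = vals[ok, k]
        frac = np.clip((v0 - 0.5) / np.maximum(v0 - v1, 1e-9), 0.0, 1.0)
        t_cross[ok] = ts[k - 1] + frac * step
        half[sign] = t_cross
    widths = half[1.0] + half[-1.0]
    return widths


def estimate_calibers(graph: VesselGraph, mask: np.ndarray) -> VesselGraph:
    """Attach per-point calibers from the distance transform of the mask.

    caliber = 2 x EDT of the mask, sampled at the *smoothed* centerline
    position corresponding to each raw point.  Raw skeleton pixels jitter
    up to half a pixel off the true vessel axis, which systematically
    shrinks the distance reading; a short moving average restores the axis
    position, at which 2 x EDT reads a rendered width-w stroke back as w
    within about half a pixel across orientations.  Points within one local
    caliber of either segment tip are flagged so caliber statistics can
    exclude the tapered stroke ends.
    """
    m = np.asarray(mask).astype(bool)
    if m.shape != tuple(graph.frame_shape):
        raise FrameMismatch(
            f"mask shape {m.shape} != graph frame {graph.frame_shape}"
        )
    edt = ndi.distance_transform_edt(m)
    mf = m.astype(float)
    for seg in graph.segments:
        pts = np.asarray(seg.points, float)
        smooth = smooth_polyline(pts, 11)
        coords = np.stack([smooth[:, 1], smooth[:, 0]])
        cal = 2.0 * ndi.map_coordinates(edt, coords, order=1)
        # second pass: thick vessels carry proportionally longer skeleton
        # wiggles, so the axis-restoring window must grow with the caliber
        med = float(np.median(cal)) if len(cal) else 0.0
        win = int(round(max(11.0, 1.2 * med)))
        win += win % 2 == 0
        if win > 11:
            smooth = smooth_polyline(pts, win)
            cal = 2.0 * ndi.map_coordinates(
                edt, np.stack([smooth[:, 1], smooth[:, 0]]), order=1
            )
        refined = _perpendicular_widths(mf, smooth, cal)
        seg.calibers = np.where(np.isfinite(refined), refined, cal)
        s = cumulative_arclength(pts)
        from_tip = np.minimum(s, s[-1] - s)
        # exclude one *representative* caliber at each end: the local
        # caliber shrinks where a vessel tapers off, which would otherwise
        # defeat the exclusion exactly where it matters
        ref = float(np.median(seg.calibers)) if len(seg.calibers) else 0.0
        seg.tip = from_tip < max(ref, 1.0)
    return graph


def prune_graph(graph: VesselGraph, min_length_px: float = 15.0) -> VesselGraph:
    """Remove terminal segments shorter than `min_length_px`, re-merge
    degree-2 chains, and iterate to a fixed point (hence idempotent)."""
    nodes = {k: Node(n.id, n.position.copy(), n.kind, n.degree) for k, n in graph.nodes.items()}
    segs = [
        Segment(
            points=np.asarray(s.points, float).copy(),
            u=s.u,
            v=s.v,
            calibers=None if s.calibers is None else np.asarray(s.calibers).copy(),
            tip=None if s.tip is None else np.asarray(s.tip).copy(),
            closed=s.closed,
        )
        for s in graph.segments
    ]

    def degrees():
        deg = {k: 0 for k in nodes}
        for s in segs:
            if s.closed:
                continue
            deg[s.u] += 1
            deg[s.v] += 1
        return deg

    changed = True
    while changed:
        changed = False
        deg = degrees()
        keep = []
        for s in segs:
            terminal = not s.closed and (deg[s.u] == 1 or deg[s.v] == 1)
            tiny_loop = (s.closed or s.u == s.v) and s.length < min_length_px
            if (terminal or tiny_loop) and s.length < min_length_px:
                changed = True
                continue
            keep.append(s)
        segs = keep
        # merge chains at degree-2 nodes
        deg = degrees()
        for nid, d in deg.items():
            if d != 2 or nodes[nid].kind == "endpoint" and d != 2:
                pass
            if d != 2:
                continue
            incident = [s for s in segs if not s.closed and nid in (s.u, s.v)]
            if len(incident) == 1:
                # same segment twice: a loop through this node; flag closed
                s = incident[0]
                if s.u == nid and s.v == nid:
                    s.closed = True
                    changed = True
                continue
            if len(incident) != 2:
                continue
            a, b = incident
            # orient a to end at nid, b to start at nid
            if a.u == nid:
                a.points = a.points[::-1]
                if a.calibers is not None:
                    a.calibers = a.calibers[::-1]
                if a.tip is not None:
                    a.tip = a.tip[::-1]
                a.u, a.v = a.v, a.u
            if b.v == nid:
                b.points = b.points[::-1]
                if b.calibers is not None:
                    b.calibers = b.calibers[::-1]
                if b.tip is not None:
                    b.tip = b.tip[::-1]
                b.u, b.v = b.v, b.u
            merged = Segment(
                points=np.vstack([a.points, b.points[1:]]),
                u=a.u,
                v=b.v,
                calibers=None
                if a.calibers is None or b.calibers is None
                else np.concatenate([a.calibers, b.calibers[1:]]),
                tip=None
                if a.tip is None or b.tip is None
                else np.concatenate([a.tip, b.tip[1:]]),
                closed=a.u == b.v,
            )
            segs = [s for s in segs if s is not a and s is not b] + [merged]
            changed = True

    used = {s.u for s in segs} | {s.v for s in segs}
    out = VesselGraph(
        nodes={k: nodes[k] for k in used},
        segments=segs,
        vessel_class=graph.vessel_class,
        frame_shape=graph.frame_shape,
    )
    out.recompute_degrees()
    for n in out.nodes.values():
        n.kind = "branchpoint" if n.degree >= 3 else "endpoint"
    return out


def mask_to_graph(
    mask: np.ndarray,
    vessel_class: str = "vessel",
    min_length_px: float = 15.0,
) -> VesselGraph:
    """Convenience pipeline: skeletonize → build → prune → calibers.

    Calibers are estimated after pruning so tip flags refer to the tips of
    the merged segments, not to removed spurs.
    """
    skel = skeletonize(mask)
    g = build_graph(skel, vessel_class)
    g = prune_graph(g, min_length_px)
    g = estimate_calibers(g, mask)
    return g
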