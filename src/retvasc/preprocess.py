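"""Fundus field-of-view detection, canonical cropping and contrast enhancement.

A color fundus image (CFI) shows a bright, roughly circular field of view
(FOV) on a dark background; the circle is often truncated flat where it
extends past the sensor edges.  This module detects that geometry, crops the
image to the tight square around the FOV, resizes it to a canonical square
frame, and computes a center-surround contrast-enhanced companion image.
The cropped and enhanced images together form the six-channel stack consumed
by downstream segmentation models.

Coordinate convention: (x = column, y = row), 0-based, pixel centers at
integer coordinates.  Intensities are handled as floats in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .errors import DegenerateBounds, NoFundusDetected

__all__ = [
    "FundusBounds",
    "FrameTransform",
    "PreprocessConfig",
    "PreprocessedCFI",
    "detect_bounds",
    "crop_and_resize",
    "enhance_contrast",
    "preprocess",
    "resample_mask",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class FundusBounds:
    """Field-of-view geometry: a circle plus up to four clipping lines.

    A line is present only where the FOV is truncated flat at the
    corresponding image edge.  `top`/`bottom` are row coordinates (the FOV
    lies at rows >= top and <= bottom); `left`/`right` are column
    coordinates (FOV at columns >= left and <= right).
    """

    center_x: float
    center_y: float
    radius: float
    top: Optional[float] = None
    bottom: Optional[float] = None
    left: Optional[float] = None
    right: Optional[float] = None

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        for name, off, coord in (
            ("top", self.top, self.center_y),
            ("bottom", self.bottom, self.center_y),
            ("left", self.left, self.center_x),
            ("right", self.right, self.center_x),
        ):
            if off is not None and abs(off - coord) >= self.radius:
                raise ValueError(f"{name} line does not intersect the FOV circle")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.center_x, self.center_y])

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean raster of the bounded region (circle ∩ half-planes)."""
        h, w = shape[:2]
        yy, xx = np.mgrid[0:h, 0:w]
        m = (xx - self.center_x) ** 2 + (yy - self.center_y) ** 2 <= self.radius**2
        if self.top is not None:
            m &= yy >= self.top
        if self.bottom is not None:
            m &= yy <= self.bottom
        if self.left is not None:
            m &= xx >= self.left
        if self.right is not None:
            m &= xx <= self.right
        return m

    def transformed(self, t: "FrameTransform") -> "FundusBounds":
        cx, cy = t.forward(np.array([[self.center_x, self.center_y]]))[0]
        return FundusBounds(
            center_x=cx,
            center_y=cy,
            radius=self.radius * t.scale,
            top=None if self.top is None else self.top * t.scale + t.offset_y,
            bottom=None if self.bottom is None else self.bottom * t.scale + t.offset_y,
            left=None if self.left is None else self.left * t.scale + t.offset_x,
            right=None if self.right is None else self.right * t.scale + t.offset_x,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "FundusBounds":
        return cls(**json.loads(s))


@dataclass
class FrameTransform:
    """Similarity map between the source frame and the canonical frame.

    forward(p) = scale * p + (offset_x, offset_y), applied to (x, y) points.
    """

    scale: float
    offset_x: float
    offset_y: float
    source_size: tuple[int, int] = (0, 0)  # (height, width)
    target_size: int = 0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive (invertibility)")

    @property
    def offset(self) -> np.ndarray:
        return np.array([self.offset_x, self.offset_y])

    def forward(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) * self.scale + self.offset

    def inverse(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.offset) / self.scale

    def to_json(self) -> str:
        d = asdict(self)
        d["source_size"] = list(self.source_size)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "FrameTransform":
        d = json.loads(s)
        d["source_size"] = tuple(d.get("source_size", (0, 0)))
        return cls(**d)


@dataclass
class PreprocessConfig:
    target_size: int = 1024
    enhance_sigma_fraction: float = 0.05
    enhance_gain: float = 4.0
    enhance_offset: float = 0.5
    min_fov_fraction: float = 0.05
    # bounds detection knobs
    threshold_fraction: float = 0.05
    edge_line_fraction: float = 0.02

    def __post_init__(self):
        if self.target_size < 64:
            raise ValueError("target_size must be >= 64")
        if not 0 < self.enhance_sigma_fraction < 0.5:
            raise ValueError("enhance_sigma_fraction must be in (0, 0.5)")
        if not 0 < self.enhance_offset < 1:
            raise ValueError("enhance_offset must be in (0, 1)")


@dataclass
class PreprocessedCFI:
    cropped: np.ndarray
    enhanced: np.ndarray
    bounds_in_target: FundusBounds
    transform: FrameTransform

    @property
    def six_channel(self) -> np.ndarray:
        """Channel stack (cropped RGB, enhanced RGB) along the last axis."""
        return np.concatenate([self.cropped, self.enhanced], axis=-1)


# ---------------------------------------------------------------------------
# helpers


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB raster of shape (h, w, 3)")
    if min(img.shape[:2]) < 64:
        raise ValueError("image min side must be >= 64 px")
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    return np.clip(img.astype(float), 0.0, 1.0)


def _fit_circle(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit."""
    a = np.column_stack([xs, ys, np.ones_like(xs)])
    b = xs**2 + ys**2
    (cx2, cy2, c), *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy = cx2 / 2.0, cy2 / 2.0
    r = np.sqrt(max(c + cx**2 + cy**2, 0.0))
    return float(cx), float(cy), float(r)


# ---------------------------------------------------------------------------
# operations


def detect_bounds(
    image: np.ndarray, config: PreprocessConfig | None = None
) -> FundusBounds:
    """Detect the fundus field of view: a circle plus optional edge lines.

    The max-channel intensity is thresholded at `threshold_fraction` of its
    robust (99th percentile) maximum, the largest connected component is
    taken as the FOV candidate, and a circle is least-squares fitted to its
    boundary pixels, excluding pixels lying on image edges.  An edge line is
    declared where at least `edge_line_fraction` of the boundary pixels lie
    on that image edge, and placed at the extreme occupied row/column.

    Raises :class:`NoFundusDetected` if no candidate covers at least
    `min_fov_fraction` of the image area.
    """
    cfg = config or PreprocessConfig()
    img = _as_float_rgb(image)
    h, w = img.shape[:2]
    intensity = img.max(axis=2)
    robust_max = float(np.percentile(intensity, 99.0))
    thr = max(cfg.threshold_fraction * robust_max, 1e-3)
    fg = intensity > thr
    if not fg.any():
        raise NoFundusDetected("no pixels above the FOV threshold")
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    comp = labels == int(np.argmax(counts))
    if comp.sum() < cfg.min_fov_fraction * h * w:
        raise NoFundusDetected(
            f"largest bright component covers {comp.sum() / (h * w):.3%} "
            f"< min_fov_fraction={cfg.min_fov_fraction}"
        )

    boundary = comp & ~ndi.binary_erosion(comp, structure=np.ones((3, 3)))
    by, bx = np.nonzero(boundary)
    n_boundary = len(by)

    rows = np.nonzero(comp.any(axis=1))[0]
    cols = np.nonzero(comp.any(axis=0))[0]
    on_top, on_bottom = by == 0, by == h - 1
    on_left, on_right = bx == 0, bx == w - 1
    frac = cfg.edge_line_fraction
    top = float(rows[0]) if on_top.sum() >= frac * n_boundary else None
    bottom = float(rows[-1]) if on_bottom.sum() >= frac * n_boundary else None
    left = float(cols[0]) if on_left.sum() >= frac * n_boundary else None
    right = float(cols[-1]) if on_right.sum() >= frac * n_boundary else None

    interior = ~(on_top | on_bottom | on_left | on_right)
    # also drop pixels adjacent to a detected flat edge: they sit on the line,
    # not the circle
    if top is not None:
        interior &= by > top + 1
    if bottom is not None:
        interior &= by < bottom - 1
    if left is not None:
        interior &= bx > left + 1
    if right is not None:
        interior &= bx < right - 1
    if interior.sum() < 16:
        raise NoFundusDetected("too few circular boundary pixels to fit the FOV")
    cx, cy, r = _fit_circle(bx[interior].astype(float), by[interior].astype(float))
    # boundary pixel centers lie ~half a pixel inside the true circle
    r += 0.5
    return FundusBounds(cx, cy, r, top=top, bottom=bottom, left=left, right=right)


def _bounded_bbox(bounds: FundusBounds, shape: tuple[int, int]) -> tuple[float, ...]:
    h, w = shape[:2]
    x0 = bounds.center_x - bounds.radius
    x1 = bounds.center_x + bounds.radius
    y0 = bounds.center_y - bounds.radius
    y1 = bounds.center_y + bounds.radius
    if bounds.left is not None:
        x0 = max(x0, bounds.left)
    if bounds.right is not None:
        x1 = min(x1, bounds.right)
    if bounds.top is not None:
        y0 = max(y0, bounds.top)
    if bounds.bottom is not None:
        y1 = min(y1, bounds.bottom)
    x0, x1 = max(x0, 0.0), min(x1, w - 1.0)
    y0, y1 = max(y0, 0.0), min(y1, h - 1.0)
    return x0, x1, y0, y1


def crop_and_resize(
    image: np.ndarray,
    bounds: FundusBounds,
    config: PreprocessConfig | None = None,
    *,
    order: int = 1,
) -> tuple[np.ndarray, FrameTransform, FundusBounds]:
    """Map the tight square around the bounded region onto a canonical frame.

    Returns the resampled raster (bilinear by default; pass order=0 for
    label masks), the source→target :class:`FrameTransform`, and the bounds
    re-expressed in the target frame.
    """
    cfg = config or PreprocessConfig()
    img = np.asarray(image)
    x0, x1, y0, y1 = _bounded_bbox(bounds, img.shape[:2])
    side = max(x1 - x0, y1 - y0)
    if side <= 0:
        raise DegenerateBounds("bounding square has zero side")
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    scale = cfg.target_size / side
    sq_min_x, sq_min_y = cx - side / 2.0, cy - side / 2.0
    t = FrameTransform(
        scale=scale,
        offset_x=-sq_min_x * scale,
        offset_y=-sq_min_y * scale,
        source_size=img.shape[:2],
        target_size=cfg.target_size,
    )
    n = cfg.target_size
    tgt = np.arange(n)
    src_x = (tgt - t.offset_x) / scale
    src_y = (tgt - t.offset_y) / scale
    sx, sy = np.meshgrid(src_x, src_y)
    coords = np.stack([sy.ravel(), sx.ravel()])
    if img.ndim == 2:
        out = ndi.map_coordinates(img.astype(float), coords, order=order, cval=0.0)
        out = out.reshape(n, n)
    else:
        chans = [
            ndi.map_coordinates(
                img[..., c].astype(float), coords, order=order, cval=0.0
            ).reshape(n, n)
            for c in range(img.shape[2])
        ]
        out = np.stack(chans, axis=-1)
    return out, t, bounds.transformed(t)


def resample_mask(mask: np.ndarray, transform: FrameTransform) -> np.ndarray:
    """Re-express an integer label mask in the target frame (nearest-neighbor)."""
    n = transform.target_size
    tgt = np.arange(n)
    sx = (tgt - transform.offset_x) / transform.scale
    sy = (tgt - transform.offset_y) / transform.scale
    gx, gy = np.meshgrid(sx, sy)
    coords = np.stack([gy.ravel(), gx.ravel()])
    out = ndi.map_coordinates(
        np.asarray(mask), coords, order=0, cval=0, mode="constant"
    )
    return out.reshape(n, n).astype(np.asarray(mask).dtype)


def _mirror_fill(img: np.ndarray, bounds: FundusBounds) -> np.ndarray:
    """Fill the exterior of the FOV with interior content mirrored across
    the FOV boundary (flat edges first, then radially across the circle)."""
    out = img.astype(float).copy()
    h, w = out.shape[:2]
    # reflect across flat clipping lines
    for axis_is_row, off, lo in (
        (True, bounds.top, True),
        (True, bounds.bottom, False),
        (False, bounds.left, True),
        (False, bounds.right, False),
    ):
        if off is None:
            continue
        o = int(round(off))
        if axis_is_row:
            idx = np.arange(h)
            refl = np.clip(2 * o - idx, 0, h - 1)
            sel = idx < o if lo else idx > o
            out[sel] = out[refl[sel]]
        else:
            idx = np.arange(w)
            refl = np.clip(2 * o - idx, 0, w - 1)
            sel = idx < o if lo else idx > o
            out[:, sel] = out[:, refl[sel]]
    # radial reflection across the circle
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - bounds.center_x, yy - bounds.center_y
    rr = np.hypot(dx, dy)
    outside = rr > bounds.radius
    if outside.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            mr = np.clip(2 * bounds.radius - rr, 0.0, None)
            f = np.where(rr > 0, mr / rr, 0.0)
        sx = bounds.center_x + dx * f
        sy = bounds.center_y + dy * f
        coords = np.stack([sy[outside], sx[outside]])
        if out.ndim == 2:
            out[outside] = ndi.map_coordinates(out, coords, order=1, mode="nearest")
        else:
            for c in range(out.shape[2]):
                out[..., c][outside] = ndi.map_coordinates(
                    out[..., c], coords, order=1, mode="nearest"
                )
    return out


def enhance_contrast(
    image: np.ndarray,
    bounds: FundusBounds,
    config: PreprocessConfig | None = None,
) -> np.ndarray:
    """Center-surround contrast enhancement within the FOV.

    enhanced = clip(gain * (I - G_sigma(I)) + offset, 0, 1) per channel,
    computed after mirroring interior content across the FOV boundary (to
    avoid halo artifacts at the dark exterior), with the exterior blacked
    out afterwards.  sigma = enhance_sigma_fraction * target_size.
    """
    cfg = config or PreprocessConfig()
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if img.dtype != float:
        img = img.astype(float)
    sigma = cfg.enhance_sigma_fraction * cfg.target_size
    mirrored = _mirror_fill(img, bounds)
    if mirrored.ndim == 2:
        blurred = ndi.gaussian_filter(mirrored, sigma)
    else:
        blurred = np.stack(
            [ndi.gaussian_filter(mirrored[..., c], sigma) for c in range(3)], axis=-1
        )
    enhanced = np.clip(
        cfg.enhance_gain * (mirrored - blurred) + cfg.enhance_offset, 0.0, 1.0
    )
    inside = bounds.mask(img.shape[:2])
    enhanced[~inside] = 0.0
    return enhanced


def preprocess(
    image: np.ndarray, config: PreprocessConfig | None = None
) -> PreprocessedCFI:
    """detect_bounds → crop_and_resize → enhance_contrast, composed."""
    cfg = config or PreprocessConfig()
    img = _as_float_rgb(image)
    bounds = detect_bounds(img, cfg)
    cropped, transform, bounds_t = crop_and_resize(img, bounds, cfg, order=1)
    enhanced = enhance_contrast(cropped, bounds_t, cfg)
    return PreprocessedCFI(
        cropped=cropped,
        enhanced=enhanced,
        bounds_in_target=bounds_t,
        transform=transform,
    )
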