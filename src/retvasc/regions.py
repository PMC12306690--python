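"""Anatomical regions scoping feature measurement.

All region geometry is expressed in disc diameters (DD), the equivalent
diameter of the optic disc mask, which serves as the anatomical scale unit
when device metadata (mm per pixel) is unavailable.  The classical CRE
measurement zone is "zone B": the peripapillary annulus 0.5-1.0 DD from the
disc margin, i.e. radii [1.0, 1.5]·DD from the disc center.  When a
millimetre scale is needed (ETDRS grid), a nominal disc diameter of 1.8 mm
is assumed; both choices are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import EmptyDisc
from .preprocess import FundusBounds

__all__ = [
    "DiscGeometry",
    "RegionMask",
    "RegionConfig",
    "disc_geometry",
    "measurement_zone",
    "fov_region",
    "etdrs_grid",
]


@dataclass
class DiscGeometry:
    """Optic disc center and equivalent diameter (the scale unit DD)."""

    center_x: float
    center_y: float
    dd: float  # equivalent diameter, px

    def __post_init__(self):
        if self.dd <= 0:
            raise ValueError("disc diameter must be positive")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.center_x, self.center_y])


@dataclass
class RegionMask:
    mask: np.ndarray  # bool raster
    name: str
    radii_dd: tuple[float, ...] = ()  # defining radii in DD units

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class RegionConfig:
    zone_b_inner: float = 1.0  # DD from disc center (= 0.5 DD from margin)
    zone_b_outer: float = 1.5
    arcade_circle_radius: float = 1.5  # DD, circle on which arcades are sampled
    mm_per_dd: float = 1.8  # nominal anatomical scale

    def __post_init__(self):
        if not 0 < self.zone_b_inner < self.zone_b_outer:
            raise ValueError("require 0 < zone_b_inner < zone_b_outer")


def disc_geometry(disc_mask: np.ndarray) -> DiscGeometry:
    """Centroid and equivalent diameter of the largest disc component."""
    m = np.asarray(disc_mask).astype(bool)
    if not m.any():
        raise EmptyDisc("disc mask has no foreground pixels")
    labels, n = ndi.label(m)
    if n > 1:
        warnings.warn(
            f"disc mask has {n} components; using the largest", stacklevel=2
        )
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        m = labels == int(np.argmax(counts))
    ys, xs = np.nonzero(m)
    area = len(ys)
    dd = 2.0 * np.sqrt(area / np.pi)
    return DiscGeometry(center_x=float(xs.mean()), center_y=float(ys.mean()), dd=dd)


def _radial_distance(shape: tuple[int, int], center: np.ndarray) -> np.ndarray:
    h, w = shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    return np.hypot(xx - center[0], yy - center[1])


def measurement_zone(
    disc: DiscGeometry,
    frame_shape: tuple[int, int],
    config: RegionConfig | None = None,
) -> RegionMask:
    """Peripapillary annulus (zone B by default) about the disc center."""
    cfg = config or RegionConfig()
    rr = _radial_distance(frame_shape, disc.center)
    inner, outer = cfg.zone_b_inner * disc.dd, cfg.zone_b_outer * disc.dd
    return RegionMask(
        mask=(rr >= inner) & (rr <= outer),
        name="zone_b",
        radii_dd=(cfg.zone_b_inner, cfg.zone_b_outer),
    )


def fov_region(
    bounds: FundusBounds,
    disc: DiscGeometry | None,
    frame_shape: tuple[int, int],
) -> RegionMask:
    """The field of view, minus the disc interior when disc geometry is given."""
    m = bounds.mask(frame_shape)
    if disc is not None:
        rr = _radial_distance(frame_shape, disc.center)
        m = m & (rr > disc.dd / 2.0)
    return RegionMask(mask=m, name="fov" if disc is None else "fov_minus_disc")


def etdrs_grid(
    fovea: tuple[float, float],
    px_per_dd: float,
    frame_shape: tuple[int, int],
    config: RegionConfig | None = None,
) -> list[RegionMask]:
    """The 9 ETDRS subfields centered on the fovea.

    Concentric rings of diameter 1, 3 and 6 mm (converted to px through the
    nominal 1 DD = mm_per_dd scale); the two outer rings are split into
    superior / nasal-right / inferior / temporal-left quadrants by the
    diagonals through the fovea.  Subfields partition the 6-mm disk.
    """
    cfg = config or RegionConfig()
    px_per_mm = px_per_dd / cfg.mm_per_dd
    fx, fy = float(fovea[0]), float(fovea[1])
    h, w = frame_shape[:2]
    if not (0 <= fx < w and 0 <= fy < h):
        raise ValueError("fovea must lie inside the frame")
    rr = _radial_distance(frame_shape, np.array([fx, fy]))
    r1, r3, r6 = 0.5 * px_per_mm, 1.5 * px_per_mm, 3.0 * px_per_mm
    yy, xx = np.mgrid[0:h, 0:w]
    ang = np.degrees(np.arctan2(yy - fy, xx - fx))  # y-down: positive = below
    quads = {
        "right": (ang >= -45) & (ang < 45),
        "inferior": (ang >= 45) & (ang < 135),
        "left": (ang >= 135) | (ang < -135),
        "superior": (ang >= -135) & (ang < -45),
    }
    out = [RegionMask(rr <= r1, "center", (0.5 / cfg.mm_per_dd,))]
    inner = (rr > r1) & (rr <= r3)
    outer = (rr > r3) & (rr <= r6)
    for ring_name, ring, radii in (
        ("inner", inner, (0.5 / cfg.mm_per_dd, 1.5 / cfg.mm_per_dd)),
        ("outer", outer, (1.5 / cfg.mm_per_dd, 3.0 / cfg.mm_per_dd)),
    ):
        for qname, q in quads.items():
            out.append(RegionMask(ring & q, f"{ring_name}_{qname}", radii))
    return out
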