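"""Gaussian heatmap encoding/decoding for keypoint (fovea) localization.

A keypoint is encoded as H(p) = exp(-||p - kp||^2 / (2 sigma^2)) on the
target raster (peak normalized to 1); decoding reads the 2D argmax, with
row-major first occurrence breaking ties.  The constant-sigma Gaussian with
sigma = 50 px on a 512 x 512 raster is the standard target construction for
MSE-trained heatmap regression of the fovea.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyHeatmap, FrameMismatch, OutOfFrame

__all__ = ["Keypoint", "Heatmap", "encode_heatmap", "decode_heatmap", "localization_error"]

DEFAULT_SHAPE = (512, 512)
DEFAULT_SIGMA = 50.0


@dataclass
class Keypoint:
    x: float
    y: float
    frame: tuple[int, int] = DEFAULT_SHAPE  # (height, width)
    low_confidence: bool = False


@dataclass
class Heatmap:
    data: np.ndarray
    sigma: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def encode_heatmap(
    kp: Keypoint,
    sigma: float = DEFAULT_SIGMA,
    shape: tuple[int, int] = DEFAULT_SHAPE,
) -> Heatmap:
    """Gaussian with constant sigma centered at the keypoint, peak 1."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    h, w = shape
    if not (0 <= kp.x < w and 0 <= kp.y < h):
        raise OutOfFrame(f"keypoint ({kp.x}, {kp.y}) outside frame {shape}")
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (xx - kp.x) ** 2 + (yy - kp.y) ** 2
    return Heatmap(data=np.exp(-d2 / (2.0 * sigma**2)), sigma=float(sigma))


def decode_heatmap(hm: Heatmap) -> Keypoint:
    """Keypoint at the heatmap maximum (row-major first occurrence on ties).

    A flat heatmap has no information; its argmax is still returned but the
    keypoint is flagged low-confidence.
    """
    data = np.asarray(hm.data, dtype=float)
    if data.size == 0 or not np.isfinite(data).any():
        raise EmptyHeatmap("heatmap is empty or all-invalid")
    flat_idx = int(np.nanargmax(data))
    y, x = np.unravel_index(flat_idx, data.shape)
    flat = bool(np.nanmax(data) - np.nanmin(data) < 1e-12)
    return Keypoint(x=float(x), y=float(y), frame=data.shape, low_confidence=flat)


def localization_error(pred: Keypoint, truth: Keypoint) -> float:
    """Euclidean (L2) distance between two keypoints in the same frame."""
    if tuple(pred.frame) != tuple(truth.frame):
        raise FrameMismatch(f"frames differ: {pred.frame} vs {truth.frame}")
    return float(np.hypot(pred.x - truth.x, pred.y - truth.y))
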