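"""Readers and writers for the package's file formats.

Images are 8-bit PNG/TIFF/JPEG RGB (intensities mapped to [0,1] floats
in memory); binary and label masks are single-channel PNG (A/V labels as a
paletted PNG with indices 0-3); geometry sidecars (bounds, transforms,
keypoints) are JSON; feature tables are CSV with the 24 canonical columns
plus a `<feature>__reason` column for each missing value.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .biomarkers import FEATURE_NAMES, FeatureSet
from .keypoint import Keypoint
from .preprocess import FrameTransform, FundusBounds

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_av_mask",
    "read_bounds",
    "write_bounds",
    "read_keypoint",
    "write_keypoint",
    "write_heatmap",
    "read_heatmap",
    "features_to_frame",
    "write_features_csv",
    "read_features_csv",
]

_AV_PALETTE = [0, 0, 0, 220, 60, 60, 60, 60, 220, 220, 60, 220]  # bg/A/V/cross


def read_image(path) -> np.ndarray:
    """RGB image as float array in [0, 1], shape (h, w, 3)."""
    img = Image.open(path).convert("RGB")
    return np.asarray(img, dtype=float) / 255.0


def write_image(path, image: np.ndarray) -> None:
    """Write a float [0,1] (or uint8) RGB raster as 8-bit PNG."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = (np.clip(arr, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_mask(path) -> np.ndarray:
    """Single-channel integer mask (binary or 4-level labels)."""
    return np.asarray(Image.open(path).convert("P" if _is_paletted(path) else "L"))


def _is_paletted(path) -> bool:
    with Image.open(path) as im:
        return im.mode == "P"


def write_mask(path, mask: np.ndarray) -> None:
    Image.fromarray(np.asarray(mask).astype(np.uint8), mode="L").save(path)


def write_av_mask(path, labels: np.ndarray) -> None:
    """4-level A/V label raster as a paletted PNG with indices 0-3."""
    im = Image.fromarray(np.asarray(labels).astype(np.uint8), mode="P")
    im.putpalette(_AV_PALETTE)
    im.save(path)


def write_bounds(path, bounds: FundusBounds, transform: FrameTransform | None = None) -> None:
    d = json.loads(bounds.to_json())
    if transform is not None:
        d.update(json.loads(transform.to_json()))
    Path(path).write_text(json.dumps(d, indent=2))


def read_bounds(path) -> FundusBounds:
    d = json.loads(Path(path).read_text())
    keys = ("center_x", "center_y", "radius", "top", "bottom", "left", "right")
    return FundusBounds(**{k: d.get(k) for k in keys if d.get(k) is not None or k in keys[:3]})


def write_keypoint(path, kp: Keypoint) -> None:
    Path(path).write_text(
        json.dumps({"x": kp.x, "y": kp.y, "frame": list(kp.frame)})
    )


def read_keypoint(path) -> Keypoint:
    d = json.loads(Path(path).read_text())
    return Keypoint(x=float(d["x"]), y=float(d["y"]), frame=tuple(d.get("frame", (0, 0))))


def write_heatmap(path, hm) -> None:
    """Heatmap as a 32-bit float TIFF (sigma stored in the description tag)."""
    import tifffile

    tifffile.imwrite(
        path, hm.data.astype(np.float32), description=f"sigma={hm.sigma}"
    )


def read_heatmap(path):
    import tifffile

    from .keypoint import Heatmap

    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        desc = tf.pages[0].description or ""
    sigma = float(desc.split("sigma=")[-1]) if "sigma=" in desc else float("nan")
    return Heatmap(data=data, sigma=sigma)


def features_to_frame(features: dict[str, FeatureSet]) -> pd.DataFrame:
    """One row per image id, canonical 24 columns plus missing-reason columns."""
    rows = {}
    for image_id, fs in features.items():
        row = {k: (np.nan if fs[k] is None else fs[k]) for k in FEATURE_NAMES}
        for k, reason in fs.reasons.items():
            row[f"{k}__reason"] = reason
        rows[image_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    ordered = FEATURE_NAMES + [c for c in frame.columns if c.endswith("__reason")]
    return frame.reindex(columns=[c for c in ordered if c in frame.columns])


def write_features_csv(path, features: dict[str, FeatureSet]) -> None:
    features_to_frame(features).to_csv(path, index_label="image_id")


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="image_id")
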