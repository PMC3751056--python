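"""Readers and writers for images, masks, contours and config files."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml
from PIL import Image
import tifffile

from .errors import ParameterError
from .features import BinaryMask
from .preprocess import GrayImage, PipelineConfig

__all__ = [
    "read_gray", "read_mask", "write_mask", "write_gray",
    "write_contour_csv", "write_overlay", "load_config", "save_config",
]

_LUMA = np.array([0.299, 0.587, 0.114])


def _normalize(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA  # RGB(A) -> luminance
    arr = np.asarray(arr, dtype=float)
    if arr.size and arr.max() > 1.0:
        scale = 65535.0 if arr.max() > 255.0 else 255.0
        arr = arr / scale
    return np.clip(arr, 0.0, 1.0)


def read_gray(path, fov_mm: float = 6.0,
              center: Optional[Tuple[float, float]] = None) -> GrayImage:
    """Read an 8/16-bit PNG or TIFF frame, normalised to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = np.asarray(Image.open(path))
    return GrayImage(_normalize(arr), fov_mm=fov_mm, center=center)


def read_mask(path) -> BinaryMask:
    """Read a binary mask (any nonzero pixel is foreground)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)
    return BinaryMask(arr > (arr.max() / 2 if arr.max() > 1 else 0),
                      domain="cartesian")


def write_mask(path, mask: BinaryMask) -> None:
    """Write a mask as an 8-bit PNG with foreground = 255."""
    Image.fromarray((mask.pixels.astype(np.uint8) * 255)).save(path)


def write_gray(path, img: GrayImage) -> None:
    Image.fromarray(np.clip(img.pixels * 255, 0, 255).astype(np.uint8)).save(path)


def write_contour_csv(path, contour: np.ndarray) -> None:
    """Two-column CSV of the contour, x (col) then y (row), in pixels."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y"])
        for row, col in contour:
            w.writerow([f"{col:.2f}", f"{row:.2f}"])


def write_overlay(path, img: GrayImage, contour: np.ndarray) -> None:
    """Frame rendered to RGB with the contour drawn in green."""
    base = np.clip(img.pixels * 255, 0, 255).astype(np.uint8)
    rgb = np.stack([base, base, base], axis=-1)
    rr = np.clip(np.round(contour[:, 0]).astype(int), 0, img.side - 1)
    cc = np.clip(np.round(contour[:, 1]).astype(int), 0, img.side - 1)
    rgb[rr, cc] = (0, 255, 0)
    Image.fromarray(rgb).save(path)


_CONFIG_FIELDS = set(PipelineConfig.__dataclass_fields__)


def load_config(path) -> PipelineConfig:
    """Read a flat ``key = value`` / ``key: value`` config file.

    Values are parsed as YAML scalars; unknown keys are rejected.
    """
    kwargs = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, val = line.split(sep, 1)
                break
        else:
            raise ParameterError(f"{path}:{lineno}: expected 'key = value'")
        key = key.strip()
        if key not in _CONFIG_FIELDS:
            raise ParameterError(f"{path}:{lineno}: unknown config key {key!r}")
        kwargs[key] = yaml.safe_load(val.strip())
    if "center" in kwargs and kwargs["center"] is not None:
        kwargs["center"] = tuple(kwargs["center"])
    return PipelineConfig(**kwargs)


def save_config(path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        for key, val in cfg.as_dict().items():
            fh.write(f"{key} = {json.dumps(val)}\n")
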