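"""Preprocessing of display-format IVOCT frames.

Display-format TD-OCT frames come in Cartesian coordinates with two
hardware artifacts baked in: a bright catheter-reflection ring near the
image centre and thin alignment-mark lines.  This module removes the ring
(its maximum radius ``r_max_px`` is a known property of the acquisition
hardware), attenuates the marks and residual speckle with a median filter,
and resamples the frame onto a polar (r, theta) grid where the vessel wall
becomes an approximately one-dimensional band — the representation every
later stage works in.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError

__all__ = [
    "GrayImage",
    "PolarImage",
    "PipelineConfig",
    "remove_catheter_ring",
    "median_filter",
    "cartesian_to_polar",
    "polar_to_cartesian",
]


@dataclass
class GrayImage:
    """A square grayscale cross-section frame.

    Parameters
    ----------
    pixels:
        2-D float array of intensities.  Readers normalise integer images
        to [0, 1]; the pipeline itself only requires finite values.
    fov_mm:
        Physical side length of the frame in millimetres (6 mm for the
        display format this tool targets).
    center:
        (row, col) of the catheter axis in pixel coordinates.  Defaults to
        the geometric image centre, which is where display-format frames
        place the catheter.
    """

    pixels: np.ndarray
    fov_mm: float = 6.0
    center: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ParameterError("image must be a square 2-D array")
        if self.pixels.shape[0] < 3:
            raise ParameterError("image side must be at least 3 px")
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("image intensities must be finite")
        if not self.fov_mm > 0:
            raise ParameterError("fov_mm must be positive")
        if self.center is None:
            c = (self.side - 1) / 2.0
            self.center = (c, c)
        r, c = self.center
        if not (0 <= r <= self.side - 1 and 0 <= c <= self.side - 1):
            raise ParameterError("center must lie inside the image")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    @property
    def px_mm(self) -> float:
        """Millimetres per pixel."""
        return self.fov_mm / self.side


@dataclass
class PolarImage:
    """A frame resampled onto an (r, theta) grid.

    Axis 0 is radius (row 0 = catheter axis, increasing outward), axis 1 is
    angle (column 0 = east, increasing counter-clockwise in display
    coordinates, one full turn exactly).  Geometry of the source Cartesian
    frame is retained so the transform can be inverted consistently.
    """

    pixels: np.ndarray
    r_scale_px: float            # Cartesian px per radial sample
    src_side: int                # side of the source Cartesian frame
    src_center: Tuple[float, float]
    fov_mm: float = 6.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ParameterError("polar image must be 2-D")
        if self.n_r < 2 or self.n_theta < 8:
            raise ParameterError("polar grid too small (need n_r >= 2, n_theta >= 8)")
        if not self.r_scale_px > 0:
            raise ParameterError("r_scale_px must be positive")

    @property
    def n_r(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_theta(self) -> int:
        return self.pixels.shape[1]

    @property
    def r_scale_mm(self) -> float:
        """Millimetres per radial sample."""
        return self.r_scale_px * self.fov_mm / self.src_side


@dataclass
class PipelineConfig:
    """Tunable parameters of the segmentation pipeline.

    ``r_max_px`` is the catheter-ring maximum radius r_Max; it doubles as the
    diameter D of the adaptive closing element in the polar reconstruction.
    ``gap_k`` is the multiplier of the derivative standard deviation used to
    detect branch-shadow gaps (the 5-SD rule).
    """

    r_max_px: int = 30
    median_window: int = 5
    n_r: int = 200
    n_theta: int = 630
    se_small_diam_px: int = 3
    gap_k: float = 5.0
    fov_mm: float = 6.0
    gap_correction: bool = True
    center: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.r_max_px < 1:
            raise ParameterError("r_max_px must be >= 1")
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ParameterError("median_window must be an odd integer >= 3")
        if self.n_r < 2 or self.n_theta < 8:
            raise ParameterError("polar grid too small")
        if not self.gap_k > 0:
            raise ParameterError("gap_k must be positive")
        if not self.fov_mm > 0:
            raise ParameterError("fov_mm must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


def remove_catheter_ring(img: GrayImage, r_max_px: float) -> GrayImage:
    """Zero every pixel within ``r_max_px`` of the catheter axis.

    The catheter reflection has a known location and maximum radius, so it
    is erased outright rather than detected.  Idempotent; never increases
    any intensity.
    """
    if r_max_px < 0 or r_max_px >= img.side / 2:
        raise ParameterError(
            f"r_max_px={r_max_px} out of range [0, {img.side / 2})"
        )
    rr, cc = np.indices(img.pixels.shape)
    dist = np.hypot(rr - img.center[0], cc - img.center[1])
    out = img.pixels.copy()
    out[dist <= r_max_px] = 0.0
    return GrayImage(out, fov_mm=img.fov_mm, center=img.center)


def median_filter(img: GrayImage, window: int = 5) -> GrayImage:
    """2-D median filter with edge replication.

    A 5x5 window attenuates the thin alignment-mark lines and fades
    destructive speckle without blurring the lumen border.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError("median window must be an odd integer >= 3")
    out = ndi.median_filter(img.pixels, size=window, mode="nearest")
    return GrayImage(out, fov_mm=img.fov_mm, center=img.center)


def _radial_scale(side: int, center: Tuple[float, float], n_r: int) -> float:
    """px per radial sample so that sample n_r-1 is the largest radius fully
    inside the frame (half the side for a centred catheter)."""
    r_edge = min(center[0], center[1], side - 1 - center[0], side - 1 - center[1])
    if r_edge <= 0:
        raise ParameterError("center lies on the image border")
    return r_edge / (n_r - 1)


def cartesian_to_polar(img: GrayImage, n_r: int = 200, n_theta: int = 630) -> PolarImage:
    """Resample a Cartesian frame onto the polar grid I(r, theta).

    The grid is 200 radial x 630 angular samples by default (~0.57 deg per
    A-line).  Bilinear interpolation; angle 0 points east and increases
    counter-clockwise; samples outside the frame are 0.
    """
    if n_r < 2 or n_theta < 8:
        raise ParameterError("polar grid too small")
    r_scale = _radial_scale(img.side, img.center, n_r)
    r = np.arange(n_r)[:, None] * r_scale
    theta = np.arange(n_theta)[None, :] * (2.0 * np.pi / n_theta)
    rows = img.center[0] - r * np.sin(theta)
    cols = img.center[1] + r * np.cos(theta)
    pix = ndi.map_coordinates(
        img.pixels, [rows, cols], order=1, mode="constant", cval=0.0
    )
    return PolarImage(
        pix, r_scale_px=r_scale, src_side=img.side,
        src_center=img.center, fov_mm=img.fov_mm,
    )


def polar_to_cartesian(
    pol: PolarImage,
    side_px: Optional[int] = None,
    center: Optional[Tuple[float, float]] = None,
) -> GrayImage:
    """Inverse of :func:`cartesian_to_polar`.

    Bilinear on the (r, theta) grid with the angle interpolated circularly;
    pixels beyond the maximum sampled radius are 0.
    """
    side = int(side_px) if side_px is not None else pol.src_side
    ctr = center if center is not None else pol.src_center
    if side < 2:
        raise ParameterError("side_px must be >= 2")
    rr, cc = np.indices((side, side), dtype=float)
    dy = ctr[0] - rr
    dx = cc - ctr[1]
    r_idx = np.hypot(dy, dx) / pol.r_scale_px
    th_idx = (np.arctan2(dy, dx) % (2.0 * np.pi)) / (2.0 * np.pi / pol.n_theta)
    # wrap-pad one column so theta interpolates circularly
    padded = np.concatenate(
        [np.asarray(pol.pixels, float), np.asarray(pol.pixels[:, :1], float)], axis=1
    )
    pix = ndi.map_coordinates(
        padded, [r_idx, th_idx], order=1, mode="constant", cval=0.0
    )
    return GrayImage(pix, fov_mm=pol.fov_mm, center=ctr)
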