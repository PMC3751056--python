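"""Synthetic IVOCT phantom frames with exact ground truth.

Clinical IVOCT datasets are rarely shareable, so this module renders
display-format-like frames that exercise every image feature the pipeline
has to survive: a bright vessel-wall ring with exponential depth
attenuation and unit-mean multiplicative speckle, a dark lumen, a
catheter-reflection ring of known radius, a thin alignment-mark line,
angular contrast loss from catheter offset, dim intraluminal blood/thrombus
blobs, and angular branch-shadow sectors that suppress the wall signal
entirely.  Geometry is shared with :mod:`ivoct_lumen.preprocess`, so the
recorded branch-sector columns line up with the 630-column polar grid the
pipeline uses.

The rendered intensity at radius r, angle theta (outside the lumen) is

    I = background + I_tissue * gain(theta) * exp(-mu * depth_mm) * speckle

with ``gain`` interpolating between 1 and ``gain_min`` over the circle and
``speckle`` gamma-distributed with unit mean.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Tuple

import numpy as np

from .errors import ParameterError
from .features import BinaryMask
from .preprocess import GrayImage

__all__ = ["PhantomParams", "generate_phantom", "generate_suite"]


@dataclass
class PhantomParams:
    """Full description of one synthetic frame.  ``seed`` fixes it exactly."""

    side_px: int = 400
    fov_mm: float = 6.0
    lumen_radius_mm: float = 1.5
    eccentricity: float = 0.08          # relative radius modulation, cos(theta)
    ecc_phase_deg: float = 0.0
    boundary_amp_mm: float = 0.04       # irregularity (plaque/thrombus) amplitude
    boundary_freq: int = 3
    wall_thickness_mm: float = 0.6      # bright intima/media band
    deep_tissue_factor: float = 0.35    # scattering drop beyond the wall band
    tissue_intensity: float = 0.8
    gain_min: float = 1.0               # angular gain floor (catheter offset)
    gain_phase_deg: float = 0.0
    speckle_contrast: float = 0.3       # sd/mean of multiplicative speckle
    attenuation_per_mm: float = 2.0
    catheter_ring_radius_px: float = 28.0
    catheter_ring_halfwidth_px: float = 1.5
    catheter_ring_intensity: float = 0.9
    alignment_mark: bool = True
    alignment_angle_deg: float = 30.0
    alignment_intensity: float = 0.55
    branch_sectors: Tuple[Tuple[float, float], ...] = ()  # (start_deg, width_deg)
    blob_count: int = 0
    blob_size_px: float = 4.0
    blob_intensity: float = 0.25
    background: float = 0.02
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side_px < 64:
            raise ParameterError("side_px must be >= 64")
        px_per_mm = self.side_px / self.fov_mm
        rho_max = (self.lumen_radius_mm * (1 + abs(self.eccentricity))
                   + self.boundary_amp_mm)
        if rho_max * px_per_mm >= (self.side_px - 1) / 2:
            raise ParameterError("lumen does not fit inside the field of view")
        if self.lumen_radius_mm * (1 - abs(self.eccentricity)) \
                - self.boundary_amp_mm <= 0:
            raise ParameterError("lumen radius collapses to zero")
        for start, width in self.branch_sectors:
            if not 0 < width < 180:
                raise ParameterError("branch sector width must be in (0, 180) deg")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["branch_sectors"] = [list(s) for s in self.branch_sectors]
        return d


def _boundary_radius_px(p: PhantomParams, theta: np.ndarray) -> np.ndarray:
    px_per_mm = p.side_px / p.fov_mm
    rho_mm = (p.lumen_radius_mm
              * (1 + p.eccentricity * np.cos(theta - np.deg2rad(p.ecc_phase_deg)))
              + p.boundary_amp_mm * np.sin(p.boundary_freq * theta))
    return rho_mm * px_per_mm


def generate_phantom(params: PhantomParams):
    """Render one frame.

    Returns ``(image, gold, metadata)``: the Cartesian frame, the exact
    rasterised lumen mask, and a metadata dict that records (among the
    echoed parameters) the true branch-sector column ranges on the
    630-column polar grid.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    side = p.side_px
    c = (side - 1) / 2.0
    rows, cols = np.indices((side, side), dtype=float)
    dy = c - rows
    dx = cols - c
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx) % (2.0 * np.pi)
    px_per_mm = side / p.fov_mm

    rho = _boundary_radius_px(p, theta)
    gold = r < rho

    depth_mm = np.clip(r - rho, 0.0, None) / px_per_mm
    profile = p.tissue_intensity * np.exp(-p.attenuation_per_mm * depth_mm)
    profile = np.where(depth_mm > p.wall_thickness_mm,
                       profile * p.deep_tissue_factor, profile)
    gain = p.gain_min + (1.0 - p.gain_min) * 0.5 * (
        1.0 + np.cos(theta - np.deg2rad(p.gain_phase_deg)))
    tissue = np.where(r >= rho, profile * gain, 0.0)

    # branch shadows: no wall return in these A-lines
    sector_mask = np.zeros((side, side), dtype=bool)
    theta_deg = np.rad2deg(theta)
    for start, width in p.branch_sectors:
        in_sector = (theta_deg - start) % 360.0 < width
        sector_mask |= in_sector
    tissue[sector_mask & (r >= rho)] = 0.0

    if p.speckle_contrast > 0:
        a = 1.0 / p.speckle_contrast ** 2
        speckle = rng.gamma(shape=a, scale=1.0 / a, size=(side, side))
    else:
        speckle = np.ones((side, side))
    img = p.background + tissue * speckle

    # dim intraluminal blobs (partially flushed blood / thrombus)
    for _ in range(p.blob_count):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.3, 0.7) * p.lumen_radius_mm * px_per_mm
        br = c - rad * np.sin(ang)
        bc = c + rad * np.cos(ang)
        sz = p.blob_size_px * rng.uniform(0.7, 1.3)
        blob = p.blob_intensity * np.exp(
            -((rows - br) ** 2 + (cols - bc) ** 2) / (2 * (sz / 2.0) ** 2))
        img += blob

    # catheter-reflection ring
    ring = np.abs(r - p.catheter_ring_radius_px) <= p.catheter_ring_halfwidth_px
    img[ring] = p.catheter_ring_intensity
    if p.alignment_mark:
        ang = np.deg2rad(p.alignment_angle_deg)
        # perpendicular distance to the ray at the mark angle
        d_perp = np.abs(dx * np.sin(ang) - dy * np.cos(ang))
        along = dx * np.cos(ang) + dy * np.sin(ang)
        line = (d_perp <= 0.6) & (along >= p.catheter_ring_radius_px)
        img[line] = p.alignment_intensity

    if p.noise_sigma > 0:
        img = img + rng.normal(0.0, p.noise_sigma, size=(side, side))
    img = np.clip(img, 0.0, 1.0)

    n_theta = 630
    branch_cols = []
    for start, width in p.branch_sectors:
        c0 = int(np.round(start / 360.0 * n_theta)) % n_theta
        c1 = int(np.round((start + width) / 360.0 * n_theta)) % n_theta
        branch_cols.append([c0, c1])  # half-open [c0, c1) circular
    meta = {
        "params": p.as_dict(),
        "branch_cols": branch_cols,
        "n_theta": n_theta,
        "lumen_area_px": int(gold.sum()),
    }
    return (
        GrayImage(img, fov_mm=p.fov_mm),
        BinaryMask(gold, domain="cartesian"),
        meta,
    )


def generate_suite(n: int, difficulty: str = "easy", seed: int = 0) -> List[tuple]:
    """Reproducibly draw ``n`` phantom cases.

    ``easy``: moderate speckle, mild eccentricity and boundary
    irregularity, moderate angular contrast loss, no branches.
    ``hard``: strong angular gain gradient (down to x0.2 at the far side),
    1-2 branch-shadow sectors, larger boundary perturbation, heavier
    speckle, more and brighter intraluminal blobs.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if difficulty not in ("easy", "hard"):
        raise ParameterError("difficulty must be 'easy' or 'hard'")
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n):
        common = dict(
            lumen_radius_mm=rng.uniform(1.1, 1.8),
            eccentricity=rng.uniform(0.03, 0.12),
            ecc_phase_deg=rng.uniform(0, 360),
            boundary_freq=int(rng.integers(2, 5)),
            gain_phase_deg=rng.uniform(0, 360),
            alignment_angle_deg=rng.uniform(0, 360),
            seed=int(rng.integers(0, 2 ** 31)),
        )
        if difficulty == "easy":
            p = PhantomParams(
                boundary_amp_mm=rng.uniform(0.02, 0.05),
                gain_min=rng.uniform(0.6, 0.9),
                speckle_contrast=rng.uniform(0.25, 0.35),
                blob_count=int(rng.integers(0, 3)),
                blob_intensity=0.22,
                **common,
            )
        else:
            n_br = int(rng.integers(1, 3))
            sectors = []
            for _ in range(n_br):
                sectors.append((float(rng.uniform(0, 360)),
                                float(rng.uniform(10, 35))))
            p = PhantomParams(
                boundary_amp_mm=rng.uniform(0.04, 0.08),
                gain_min=0.2,
                speckle_contrast=rng.uniform(0.4, 0.55),
                branch_sectors=tuple(sectors),
                blob_count=int(rng.integers(2, 5)),
                blob_intensity=0.3,
                **common,
            )
        cases.append(generate_phantom(p))
    return cases
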