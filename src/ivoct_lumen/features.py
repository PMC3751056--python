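"""Tissue feature extraction: wavelet packet frame + per-A-line Otsu.

A single level of an undecimated (shift-invariant) Daubechies-1 wavelet
packet frame smooths the polar frame into the approximation plane ``cA1``,
which separates tissue from lumen better than raw intensity.  Because
near-infrared return falls off with catheter-to-wall distance, the
tissue/lumen contrast varies with angle; a single global threshold then
drops low-contrast sectors.  Each polar column (a fixed-angle A-line),
however, contains exactly two populations — lumen and tissue — whatever the
absolute contrast, so Otsu's criterion is applied per column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pywt
from scipy import ndimage as ndi

from .errors import ParameterError
from .preprocess import PolarImage

__all__ = [
    "WaveletPlanes",
    "BinaryMask",
    "OtsuResult",
    "dwpf_level1",
    "otsu_threshold",
    "columnwise_otsu",
]

#: near-zero intensity range below which a sample is treated as constant
DEGENERATE_RANGE = 1e-6


@dataclass
class WaveletPlanes:
    """Level-1 undecimated wavelet frame of a polar frame.

    All four planes have the shape of the input.  ``cA1`` (low-pass both
    axes) carries the tissue information and feeds the binarisation;
    ``cH1``/``cV1``/``cD1`` are the horizontal/vertical/diagonal detail
    planes, kept for inspection.
    """

    cA1: np.ndarray
    cH1: np.ndarray
    cV1: np.ndarray
    cD1: np.ndarray


@dataclass
class BinaryMask:
    """A boolean image tagged with its coordinate domain."""

    pixels: np.ndarray
    domain: str = "polar"  # "polar" | "cartesian"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != bool:
            if not np.isin(self.pixels, (0, 1)).all():
                raise ParameterError("mask must be boolean")
            self.pixels = self.pixels.astype(bool)
        if self.pixels.ndim != 2:
            raise ParameterError("mask must be 2-D")
        if self.domain not in ("polar", "cartesian"):
            raise ParameterError("domain must be 'polar' or 'cartesian'")

    @property
    def shape(self):
        return self.pixels.shape


class OtsuResult(NamedTuple):
    threshold: float
    degenerate: bool


def _haar_filters(wavelet: str = "db1"):
    w = pywt.Wavelet(wavelet)
    lo = np.asarray(w.dec_lo, dtype=float)
    hi = np.asarray(w.dec_hi, dtype=float)
    # averaging convention: low-pass of a constant is that constant, so cA1
    # keeps the intensity scale that Otsu histograms
    s = lo.sum()
    return lo / s, hi / s


def dwpf_level1(pol, wavelet: str = "db1") -> WaveletPlanes:
    """One level of a separable undecimated wavelet packet frame.

    The a-trous variant is used so every coefficient plane stays aligned
    pixel-for-pixel with the input (no decimation).  Borders are
    edge-replicated.  With the averaging normalisation, ``cA1`` of a
    constant image is that constant and the detail planes are zero.
    """
    x = np.asarray(pol.pixels if isinstance(pol, PolarImage) else pol, dtype=float)
    if x.ndim != 2:
        raise ParameterError("input must be 2-D")
    if not np.all(np.isfinite(x)):
        raise ParameterError("input must be finite")
    lo, hi = _haar_filters(wavelet)

    def f(a, kernel, axis):
        # origin=-1 pairs sample j with j+1 for the 2-tap Haar kernels
        org = -1 if len(kernel) % 2 == 0 else 0
        return ndi.correlate1d(a, kernel, axis=axis, mode="nearest", origin=org)

    lo0 = f(x, lo, 0)
    hi0 = f(x, hi, 0)
    return WaveletPlanes(
        cA1=f(lo0, lo, 1),
        cH1=f(hi0, lo, 1),   # high-pass along rows: horizontal structure
        cV1=f(lo0, hi, 1),   # high-pass along columns: vertical structure
        cD1=f(hi0, hi, 1),
    )


def otsu_threshold(values, nbins: int = 256) -> OtsuResult:
    """Otsu's histogram threshold of a 1-D sample.

    A ``nbins``-bin histogram is built over the sample's own min-max range
    and the cut maximising the between-class variance
    ``sigma_B^2(t) = w0 * w1 * (mu0 - mu1)**2`` is selected; ties go to the
    lowest threshold.  Foreground is everything strictly greater than the
    returned threshold.  A (near-)constant sample has no two classes to
    separate: the constant comes back with ``degenerate=True``.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ParameterError("empty sample")
    if v.size < 2:
        raise ParameterError("need at least 2 samples")
    if not np.all(np.isfinite(v)):
        raise ParameterError("sample must be finite")
    vmin, vmax = float(v.min()), float(v.max())
    if (vmax - vmin) < DEGENERATE_RANGE * max(1.0, abs(vmax), abs(vmin)):
        return OtsuResult(vmin, True)
    hist, edges = np.histogram(v, bins=nbins, range=(vmin, vmax))
    hist = hist.astype(float)
    # per-bin intensity sums give exact class means for every cut
    wsum, _ = np.histogram(v, bins=nbins, range=(vmin, vmax), weights=v)
    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    m0 = np.cumsum(wsum)[:-1]
    mtot = float(v.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mtot - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where(np.isfinite(sigma_b), sigma_b, -np.inf)
    # lowest cut among (numerically) tied maxima
    top = sigma_b.max()
    k = int(np.flatnonzero(sigma_b >= top - 1e-9 * abs(top))[0])
    return OtsuResult(float(edges[k + 1]), False)


def columnwise_otsu(plane, nbins: int = 256) -> BinaryMask:
    """Binarise a polar-domain plane one column (A-line) at a time.

    Each column gets its own Otsu threshold, making the binarisation
    invariant to the angular contrast variation of IVOCT frames.  Columns
    with no intensity separation (branch shadows, pure lumen) carry no
    tissue evidence and binarise to background; the gap-correction stage
    repairs them later.
    """
    x = np.asarray(plane.pixels if hasattr(plane, "pixels") else plane, dtype=float)
    if x.ndim != 2:
        raise ParameterError("plane must be 2-D")
    out = np.zeros(x.shape, dtype=bool)
    for j in range(x.shape[1]):
        thr, degenerate = otsu_threshold(x[:, j], nbins=nbins)
        if not degenerate:
            out[:, j] = x[:, j] > thr
    return BinaryMask(out, domain="polar")
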