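"""Binary morphological reconstruction of the lumen object.

Three stages turn the noisy per-column binarisation ``cA1_bin`` into the
final Cartesian lumen mask:

1. polar reconstruction — small-disk opening, upward filling (everything
   radially deeper than the first tissue return is tissue-equivalent,
   since OCT cannot see behind the first interface), largest-component
   selection, and a closing with the adaptive diameter D = r_Max;
2. branch-opening detection and correction — a side-branch ostium leaves
   an angular run of A-lines with no tissue return; it is found as an
   outlier of the circular derivative of the per-angle boundary height and
   bridged with shape-preserving cubic Hermite interpolation;
3. Cartesian reconstruction — negate, transform back, open with the
   adaptive diameter R_min (minimum lumen radius), keep the component at
   the catheter axis, and trace the contour.

The angular axis is treated as circular throughout: component labelling,
closings, derivatives and interpolation all wrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import PchipInterpolator
from skimage import measure

from .errors import ParameterError, SegmentationError
from .features import BinaryMask
from .preprocess import PolarImage, polar_to_cartesian

__all__ = [
    "GapInterval",
    "polar_reconstruct",
    "height_signal",
    "detect_gaps",
    "correct_gaps",
    "rebuild_from_height",
    "cartesian_reconstruct",
    "extract_contour",
]


@dataclass(frozen=True)
class GapInterval:
    """A circular run of theta columns flagged as a branch-shadow gap.

    ``start`` and ``end`` are inclusive column indices; ``end < start``
    means the run wraps past column 0.
    """

    start: int
    end: int
    cause: str = "detected"

    def columns(self, n_theta: int) -> np.ndarray:
        if self.end >= self.start:
            return np.arange(self.start, self.end + 1)
        return np.concatenate(
            [np.arange(self.start, n_theta), np.arange(0, self.end + 1)]
        )

    def length(self, n_theta: int) -> int:
        return len(self.columns(n_theta))


# ---------------------------------------------------------------------------
# disk morphology via exact Euclidean distance transforms
# ---------------------------------------------------------------------------

def _disk_radius(diam_px: float) -> float:
    # discrete Euclidean disk: pixel included iff its centre lies within the
    # radius; diameter d spans d pixels across the centre row
    return max((float(diam_px) - 1.0) / 2.0, 0.0)


def binary_erode_disk(mask: np.ndarray, diam_px: float) -> np.ndarray:
    r = _disk_radius(diam_px)
    if r <= 0:
        return mask.copy()
    return ndi.distance_transform_edt(mask) > r


def binary_dilate_disk(mask: np.ndarray, diam_px: float) -> np.ndarray:
    r = _disk_radius(diam_px)
    if r <= 0:
        return mask.copy()
    return ndi.distance_transform_edt(~mask) <= r


def binary_open_disk(mask: np.ndarray, diam_px: float) -> np.ndarray:
    return binary_dilate_disk(binary_erode_disk(mask, diam_px), diam_px)


def binary_close_disk(mask: np.ndarray, diam_px: float) -> np.ndarray:
    return binary_erode_disk(binary_dilate_disk(mask, diam_px), diam_px)


def _wrap_theta(func, mask: np.ndarray, diam_px: float) -> np.ndarray:
    """Apply a disk operation with the theta axis treated circularly.

    The radial axis is padded with background at r=0 (nothing exists above
    the catheter axis) and edge-replicated at max r (the object continues
    past the imaging depth).
    """
    pad = int(np.ceil(_disk_radius(diam_px))) + 1
    m = np.pad(mask, ((0, 0), (pad, pad)), mode="wrap")
    m = np.pad(m, ((pad, 0), (0, 0)), mode="constant", constant_values=False)
    m = np.pad(m, ((0, pad), (0, 0)), mode="edge")
    out = func(m, diam_px)
    return out[pad:-pad, pad:-pad]


def _largest_component_circular(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected component with the theta axis wrapping."""
    structure = np.ones((3, 3), dtype=bool)
    lab, n = ndi.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    # union-find merge of labels touching across the theta seam
    parent = np.arange(n + 1)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    n_r = mask.shape[0]
    left = lab[:, 0]
    right = lab[:, -1]
    for i in range(n_r):
        if right[i] == 0:
            continue
        for di in (-1, 0, 1):
            k = i + di
            if 0 <= k < n_r and left[k] != 0:
                union(right[i], left[k])
    roots = np.array([find(a) for a in range(n + 1)])
    sizes = np.bincount(roots[lab.ravel()], minlength=n + 1)
    sizes[0] = 0
    keep = int(np.argmax(sizes))
    return roots[lab] == keep


# ---------------------------------------------------------------------------
# stage 1: polar reconstruction
# ---------------------------------------------------------------------------

def polar_reconstruct(
    cA1_bin: BinaryMask, r_max_px: int, se_small_diam_px: int = 3
) -> BinaryMask:
    """Build l_polar*, the complementary polar lumen object.

    Composition: opening with a 3-px disk (detaches and removes blood /
    thrombus speckle in the lumen), upward filling, retention of the
    largest circularly-8-connected component, then closing with an
    adaptive disk of diameter D = ``r_max_px`` (smooths boundary
    irregularities without connecting the object to the top of the polar
    frame).  The result is a single solid region attached to the bottom
    (max-r) edge.
    """
    if cA1_bin.domain != "polar":
        raise ParameterError("polar_reconstruct expects a polar-domain mask")
    if r_max_px < 1:
        raise ParameterError("r_max_px must be >= 1")
    m = cA1_bin.pixels
    if not m.any():
        raise SegmentationError("no tissue detected")
    opened = _wrap_theta(binary_open_disk, m, se_small_diam_px)
    if not opened.any():
        raise SegmentationError("no tissue detected")
    filled = np.maximum.accumulate(opened, axis=0)
    selected = _largest_component_circular(filled)
    closed = _wrap_theta(binary_close_disk, selected, r_max_px)
    # closing cannot be allowed to detach the object from the bottom edge
    closed |= selected
    closed = np.maximum.accumulate(closed, axis=0)
    return BinaryMask(closed, domain="polar")


# ---------------------------------------------------------------------------
# stage 2: branch-opening detection and correction
# ---------------------------------------------------------------------------

def height_signal(obj: BinaryMask) -> np.ndarray:
    """Per-column first foreground row of a polar object.

    ``h[j]`` is the smallest radius sample classified tissue at angle j —
    the lumen boundary in polar coordinates — or ``n_r`` when the column
    is empty (a shadowed A-line).
    """
    if obj.domain != "polar":
        raise ParameterError("height_signal expects a polar-domain mask")
    m = obj.pixels
    n_r = m.shape[0]
    has = m.any(axis=0)
    return np.where(has, m.argmax(axis=0), n_r).astype(int)


def detect_gaps(h: np.ndarray, k: float = 5.0) -> List[GapInterval]:
    """Find branch-shadow gaps in a boundary-height signal.

    The circular first difference ``d[j] = h[j+1] - h[j]`` is thresholded
    at ``k`` standard deviations of the whole derivative signal (k = 5 by
    default).  A shadowed run shows up as an abrupt excursion of h in
    either direction: all-foreground gap columns pull h toward the
    catheter, empty columns push it to n_r.  The above-threshold crossings
    partition the circle into arcs; a gap is a maximal run of arcs whose
    median height is an outlier against the global median (an excursion
    must exceed the same threshold to exist at all), so each gap interval
    runs from one crossing to the next opposite-sign crossing even when a
    gap shoulder is split into several same-direction steps.
    """
    h = np.asarray(h)
    n = h.size
    if n < 8:
        raise ParameterError("height signal too short")
    d = np.diff(h.astype(float), append=h[:1].astype(float))
    sd = float(d.std())
    if sd == 0.0:
        return []
    thr = k * sd
    idx = np.flatnonzero(np.abs(d) > thr)
    if idx.size < 2:
        return []  # a gap needs an entering and a leaving crossing
    m = idx.size
    global_med = float(np.median(h))
    depth_floor = max(thr, 5.0)  # ignore plateau arcs of quantisation noise
    arcs = []
    anomalous = []
    for i in range(m):
        start = (int(idx[i]) + 1) % n
        end = int(idx[(i + 1) % m]) % n
        arc = GapInterval(start, end)
        level = float(np.median(h[arc.columns(n)]))
        arcs.append(arc)
        anomalous.append(abs(level - global_med) > depth_floor)
    if all(anomalous) or not any(anomalous):
        return []
    # merge circular runs of anomalous arcs into single gap intervals
    gaps: List[GapInterval] = []
    i = 0
    while i < m:
        if not anomalous[i]:
            i += 1
            continue
        if i == 0 and anomalous[m - 1]:
            i += 1  # this run wraps; emit it from its true first arc
            continue
        j = i
        while anomalous[(j + 1) % m]:
            j += 1
        gaps.append(GapInterval(arcs[i].start, arcs[j % m].end))
        i = j + 1
    return gaps


def correct_gaps(
    h: np.ndarray,
    gaps: Sequence[GapInterval],
    n_r: Optional[int] = None,
    guard: int = 2,
) -> np.ndarray:
    """Bridge detected gaps with monotone cubic (PCHIP) interpolation.

    All columns inside each gap, plus a ``guard``-column band on each side
    (the adaptive closing can round the gap shoulders), are discarded; the
    surviving samples are interpolated on the circularly unwrapped index
    axis with a shape-preserving piecewise cubic Hermite scheme, which
    cannot overshoot.  Interpolated values are rounded and clipped to
    ``[0, n_r - 1]`` when ``n_r`` is given.
    """
    h = np.asarray(h)
    n = h.size
    if not gaps:
        return h.copy()
    bad = np.zeros(n, dtype=bool)
    for g in gaps:
        cols = g.columns(n)
        ext = np.concatenate(
            [(cols[0] - np.arange(1, guard + 1)) % n,
             cols,
             (cols[-1] + np.arange(1, guard + 1)) % n]
        )
        bad[ext] = True
    good = np.flatnonzero(~bad)
    if good.size < 4:
        raise SegmentationError("too few support columns to interpolate gaps")
    ys = h[good].astype(float)
    xs = np.concatenate([good - n, good, good + n])
    interp = PchipInterpolator(xs, np.tile(ys, 3))
    out = h.astype(float).copy()
    bad_idx = np.flatnonzero(bad)
    vals = np.rint(interp(bad_idx))
    if n_r is not None:
        vals = np.clip(vals, 0, n_r - 1)
    else:
        vals = np.maximum(vals, 0)
    out[bad_idx] = vals
    return out.astype(int)


def rebuild_from_height(h: np.ndarray, shape: Tuple[int, int]) -> BinaryMask:
    """Rasterise a height signal back into a bottom-attached polar object.

    Inverse of :func:`height_signal` for column-solid objects: column j is
    foreground exactly on rows >= h[j].
    """
    n_r, n_theta = shape
    h = np.asarray(h)
    if h.size != n_theta:
        raise ParameterError("height signal length must equal n_theta")
    rows = np.arange(n_r)[:, None]
    return BinaryMask(rows >= h[None, :], domain="polar")


# ---------------------------------------------------------------------------
# stage 3: Cartesian reconstruction and contour
# ---------------------------------------------------------------------------

def cartesian_reconstruct(
    l_polar_star: BinaryMask,
    pol: PolarImage,
    side_px: Optional[int] = None,
    center: Optional[Tuple[float, float]] = None,
    r_min_floor_px: int = 3,
) -> BinaryMask:
    """Negate l_polar*, transform to Cartesian, and polish: lumen_bin.

    The final opening uses the adaptive diameter R_min — the minimum
    radius between the catheter axis and the lumen border, in Cartesian
    pixels — which removes irregularities the domain transform drags along
    without biting into the true lumen.  R_min is floored at 3 px so the
    element never degenerates when the lumen touches the catheter.
    """
    if l_polar_star.domain != "polar":
        raise ParameterError("cartesian_reconstruct expects a polar-domain mask")
    lumen_pol = ~l_polar_star.pixels
    if not lumen_pol.any():
        raise SegmentationError("lumen not found")
    h = height_signal(l_polar_star)
    geom = PolarImage(
        lumen_pol.astype(float),
        r_scale_px=pol.r_scale_px,
        src_side=pol.src_side,
        src_center=pol.src_center,
        fov_mm=pol.fov_mm,
    )
    cart = polar_to_cartesian(geom, side_px=side_px, center=center)
    cmask = cart.pixels > 0.5
    if not cmask.any():
        raise SegmentationError("lumen not found")
    r_min_px = max(float(h.min()) * pol.r_scale_px, float(r_min_floor_px))
    opened = binary_open_disk(cmask, r_min_px)
    if not opened.any():
        raise SegmentationError("lumen not found")
    # keep the component at (or nearest to) the catheter axis
    lab, n = ndi.label(opened, structure=np.ones((3, 3), dtype=bool))
    ctr = cart.center
    ci, cj = int(round(ctr[0])), int(round(ctr[1]))
    target = lab[ci, cj]
    if target == 0:
        _, (ri, rj) = ndi.distance_transform_edt(lab == 0, return_indices=True)
        target = lab[ri[ci, cj], rj[ci, cj]]
    return BinaryMask(lab == target, domain="cartesian")


def extract_contour(lumen_bin: BinaryMask) -> np.ndarray:
    """Closed outer boundary of the lumen mask.

    Sub-pixel marching squares at level 0.5, followed by a light circular
    moving average of the vertices that removes the pixel-staircase bias of
    the raw polyline.  Returns an (N, 2) array of (row, col) vertices,
    first point repeated at the end.
    """
    m = lumen_bin.pixels
    if not m.any():
        raise SegmentationError("empty mask has no contour")
    contours = measure.find_contours(m.astype(float), 0.5)
    if not contours:
        raise SegmentationError("no contour found")
    contour = max(contours, key=len)
    closed = np.array_equal(contour[0], contour[-1])
    if closed and len(contour) > 8:
        verts = contour[:-1]
        verts = np.column_stack([
            ndi.uniform_filter1d(verts[:, k], size=5, mode="wrap")
            for k in (0, 1)
        ])
        contour = np.vstack([verts, verts[:1]])
    return contour
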