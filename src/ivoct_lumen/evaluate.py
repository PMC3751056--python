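"""Segmentation accuracy panel against gold-standard masks.

Seven values per image, mirroring how automated lumen segmentations are
benchmarked against expert tracings: TP/FP/FN area fractions normalised by
the gold-standard area (so TP + FN = 100 by construction), maximum false
positive / false negative boundary deviations in millimetres, and the
overlap ratio (Jaccard) and overlap Dice scores in percent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from typing import Iterable, List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError
from .features import BinaryMask

__all__ = [
    "SegMetrics",
    "area_fractions",
    "max_deviations",
    "overlap_scores",
    "evaluate_masks",
    "summarize",
    "write_batch_csv",
]


@dataclass
class SegMetrics:
    tp_pct: float
    fp_pct: float
    fn_pct: float
    max_fp_mm: float
    max_fn_mm: float
    or_pct: float
    od_pct: float

    def as_dict(self) -> dict:
        return asdict(self)

    FIELDS = ("tp_pct", "fp_pct", "fn_pct", "max_fp_mm", "max_fn_mm",
              "or_pct", "od_pct")


def _pixels(mask) -> np.ndarray:
    m = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)
    if m.dtype != bool:
        m = m.astype(bool)
    return m


def area_fractions(seg, gold) -> Tuple[float, float, float]:
    """(TP, FP, FN) area fractions in percent of the gold area."""
    s, g = _pixels(seg), _pixels(gold)
    if s.shape != g.shape:
        raise ParameterError("masks must have the same shape")
    ng = int(g.sum())
    if ng == 0:
        raise ParameterError("gold mask is empty")
    tp = 100.0 * np.count_nonzero(s & g) / ng
    fp = 100.0 * np.count_nonzero(s & ~g) / ng
    fn = 100.0 * np.count_nonzero(~s & g) / ng
    return tp, fp, fn


def max_deviations(seg, gold, px_mm: float) -> Tuple[float, float]:
    """Maximum boundary deviations in millimetres.

    ``max_fp_mm`` is the largest Euclidean distance from a false-positive
    pixel to the gold mask; ``max_fn_mm`` the largest distance from a
    missed gold pixel to the segmentation.  Exact distance transforms;
    set-to-set distances coincide with contour deviations for solid masks.
    """
    s, g = _pixels(seg), _pixels(gold)
    if s.shape != g.shape:
        raise ParameterError("masks must have the same shape")
    if not px_mm > 0:
        raise ParameterError("px_mm must be positive")
    fp_set = s & ~g
    fn_set = g & ~s
    if fp_set.any():
        if not g.any():
            raise ParameterError("gold mask is empty")
        max_fp = float(ndi.distance_transform_edt(~g)[fp_set].max())
    else:
        max_fp = 0.0
    if fn_set.any():
        if not s.any():
            raise ParameterError("undefined deviation: segmentation is empty")
        max_fn = float(ndi.distance_transform_edt(~s)[fn_set].max())
    else:
        max_fn = 0.0
    return max_fp * px_mm, max_fn * px_mm


def overlap_scores(seg, gold) -> Tuple[float, float]:
    """(overlap ratio, overlap Dice) in percent: Jaccard and Dice."""
    s, g = _pixels(seg), _pixels(gold)
    if s.shape != g.shape:
        raise ParameterError("masks must have the same shape")
    inter = np.count_nonzero(s & g)
    union = np.count_nonzero(s | g)
    if union == 0:
        raise ParameterError("both masks are empty")
    or_pct = 100.0 * inter / union
    od_pct = 100.0 * 2 * inter / (int(s.sum()) + int(g.sum()))
    return or_pct, od_pct


def evaluate_masks(seg, gold, px_mm: Optional[float] = None,
                   fov_mm: float = 6.0) -> SegMetrics:
    """Full seven-value accuracy panel for one mask pair.

    ``px_mm`` defaults to ``fov_mm / image_side`` (6 mm field of view).
    """
    g = _pixels(gold)
    if px_mm is None:
        px_mm = fov_mm / g.shape[1]
    tp, fp, fn = area_fractions(seg, gold)
    max_fp, max_fn = max_deviations(seg, gold, px_mm)
    o_r, o_d = overlap_scores(seg, gold)
    return SegMetrics(tp, fp, fn, max_fp, max_fn, o_r, o_d)


def summarize(metrics: Iterable[SegMetrics]) -> dict:
    """Mean and standard deviation of each metric over a batch."""
    rows = [m.as_dict() for m in metrics]
    if not rows:
        raise ParameterError("no metrics to summarise")
    out = {}
    for k in SegMetrics.FIELDS:
        vals = np.array([r[k] for r in rows], dtype=float)
        out[k] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if
                  len(vals) > 1 else 0.0}
    return out


def write_batch_csv(path, names: List[str], metrics: List[SegMetrics]) -> None:
    """Per-image rows plus mean and SD rows, as CSV."""
    summary = summarize(metrics)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image", *SegMetrics.FIELDS])
        for name, m in zip(names, metrics):
            w.writerow([name] + [f"{getattr(m, k):.4f}" for k in SegMetrics.FIELDS])
        w.writerow(["mean"] + [f"{summary[k]['mean']:.4f}" for k in SegMetrics.FIELDS])
        w.writerow(["sd"] + [f"{summary[k]['sd']:.4f}" for k in SegMetrics.FIELDS])
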