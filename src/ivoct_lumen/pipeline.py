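"""End-to-end lumen segmentation: preprocess -> features -> reconstruction.

The pipeline is fully deterministic — no randomness anywhere — so the same
frame and configuration always produce the bit-identical mask.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import __version__
from .errors import SegmentationError
from .preprocess import (
    GrayImage, PipelineConfig,
    remove_catheter_ring, median_filter, cartesian_to_polar,
)
from .features import BinaryMask, dwpf_level1, columnwise_otsu
from .morphrec import (
    polar_reconstruct, height_signal, detect_gaps,
    correct_gaps, rebuild_from_height, cartesian_reconstruct, extract_contour,
)

__all__ = ["RunReport", "run_pipeline"]


@dataclass
class RunReport:
    """What happened during one segmentation run."""

    config: dict
    version: str
    gaps: List[dict] = field(default_factory=list)
    gap_corrected: bool = False
    stage_seconds: dict = field(default_factory=dict)
    metrics: Optional[dict] = None

    def as_dict(self) -> dict:
        return {
            "config": self.config,
            "version": self.version,
            "gaps": self.gaps,
            "gap_corrected": self.gap_corrected,
            "stage_seconds": self.stage_seconds,
            "metrics": self.metrics,
        }


def run_pipeline(
    img: GrayImage,
    cfg: Optional[PipelineConfig] = None,
    stages: Optional[dict] = None,
) -> Tuple[BinaryMask, np.ndarray, RunReport]:
    """Segment the lumen of one display-format frame.

    Returns ``(lumen_bin, contour, report)``.  Pass a dict as ``stages``
    to receive every intermediate product (for debugging / figure dumps).
    Raises :class:`SegmentationError` with the failing stage named when a
    frame contains no usable tissue signal.
    """
    cfg = cfg or PipelineConfig()
    if cfg.center is not None:
        img = GrayImage(img.pixels, fov_mm=img.fov_mm, center=tuple(cfg.center))
    report = RunReport(config=cfg.as_dict(), version=__version__)
    timings = report.stage_seconds
    current = {"stage": "pipeline", "t0": 0.0}

    def _stage(name):
        current["stage"] = name
        current["t0"] = time.perf_counter()

    def _done(name):
        timings[name] = time.perf_counter() - current["t0"]

    try:
        _stage("preprocess")
        no_ring = remove_catheter_ring(img, cfg.r_max_px)
        filtered = median_filter(no_ring, cfg.median_window)
        pol = cartesian_to_polar(filtered, n_r=cfg.n_r, n_theta=cfg.n_theta)
        _done("preprocess")

        _stage("features")
        planes = dwpf_level1(pol)
        cA1_bin = columnwise_otsu(planes.cA1)
        _done("features")

        _stage("polar_reconstruction")
        l_polar_star = polar_reconstruct(
            cA1_bin, cfg.r_max_px, cfg.se_small_diam_px)
        _done("polar_reconstruction")

        _stage("gap_correction")
        h = height_signal(l_polar_star)
        gaps = detect_gaps(h, k=cfg.gap_k)
        report.gaps = [
            {"start": g.start, "end": g.end, "cause": g.cause} for g in gaps
        ]
        if gaps and cfg.gap_correction:
            h_corr = correct_gaps(h, gaps, n_r=cfg.n_r)
            l_polar_star = rebuild_from_height(h_corr, (cfg.n_r, cfg.n_theta))
            report.gap_corrected = True
        _done("gap_correction")

        _stage("cartesian_reconstruction")
        lumen_bin = cartesian_reconstruct(l_polar_star, pol)
        contour = extract_contour(lumen_bin)
        _done("cartesian_reconstruction")
    except SegmentationError as exc:
        raise SegmentationError(f"{current['stage']}: {exc}") from exc

    if stages is not None:
        stages.update(
            no_ring=no_ring, filtered=filtered, polar=pol, planes=planes,
            cA1_bin=cA1_bin, l_polar_star=l_polar_star, height=h,
        )
    return lumen_bin, contour, report
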