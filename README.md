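# ivoct-lumen

Fully automatic lumen segmentation for intravascular optical coherence
tomography (IVOCT) cross-section frames, aimed at display-format TD-OCT
images: square Cartesian frames (nominally 6 mm × 6 mm) with the catheter
reflection ring near the centre and thin alignment-mark lines.  The target
users are researchers quantifying coronary lumen geometry (stenosis,
restenosis follow-up) who need hundreds of frames per pullback segmented
without seeds or manual contours.

## Method

The pipeline combines wavelet-frame feature extraction with binary
mathematical morphology, entirely deterministically:

1. **Preprocessing.**  The catheter ring is erased inside its known maximum
   radius r_Max; a 5 × 5 median filter attenuates alignment marks and
   speckle; the frame is resampled to a polar grid I(r, θ) of 200 × 630
   samples (≈ 0.57° per A-line), where the vessel wall is a 1-D band.
2. **Feature extraction.**  One level of an undecimated Daubechies-1
   wavelet packet frame yields the approximation plane cA1; each θ-column
   (A-line) is binarised with its own Otsu threshold.  Because every
   A-line contains exactly two populations — lumen and tissue — the
   per-column histogram is bimodal regardless of the angular contrast
   variation that defeats a single global threshold.
3. **Binary morphological reconstruction.**  In the polar domain: opening
   with a ⌀3 px disk (removes blood/thrombus speckle), upward filling
   (everything radially deeper than the first tissue return is
   tissue-equivalent), largest-component selection, and closing with an
   adaptive disk of diameter D = r_Max.  The per-angle boundary height
   h(θ) is then screened for branch-shadow gaps: excursions of its
   circular derivative beyond 5 standard deviations delimit the gap, which
   is re-interpolated with shape-preserving cubic Hermite (PCHIP)
   interpolation.  Finally the object is negated, transformed back to
   Cartesian, opened with an adaptive disk of diameter R_min (the minimum
   lumen radius), and the contour is traced with sub-pixel marching
   squares.

Accuracy against a gold-standard mask G is reported as the standard
seven-value panel: TP = 100·|S∩G|/|G|, FP = 100·|S\G|/|G|,
FN = 100·|G\S|/|G| (so TP + FN = 100), the maximum false-positive /
false-negative boundary deviations in mm (exact Euclidean set distances),
the overlap ratio OR (Jaccard) and overlap Dice OD = 200·OR/(100+OR).

Because clinical IVOCT datasets are rarely shareable, the package ships a
phantom generator that renders frames with every feature the method has to
survive — depth-attenuated speckled wall, angular contrast loss, catheter
ring, alignment mark, intraluminal blobs, branch-shadow sectors — together
with the exact gold lumen mask.

## Worked example

```bash
python examples/segment_phantom.py
```

```
lumen area: 30965 px (gold 31519 px)
  tp_pct       98.242
  fp_pct        0.000
  fn_pct        1.758
  max_fp_mm     0.000
  max_fn_mm     0.021
  or_pct       98.242
  od_pct       99.113
```

On this moderately noisy phantom the traced border misses 1.8 % of the
lumen area and never strays more than 0.021 mm (≈ 1.4 px) from the true
wall.  `examples/branch_gap_correction.py` shows the bifurcation case: the
true shadow sector spans polar columns 140–184 and the detector reports
141–182; Dice is 98.1 % with gap correction versus 94.8 % without.  The
other examples demonstrate the per-column-vs-global Otsu comparison and
the metric identities.

From the shell, the same pipeline runs as:

```bash
ivoct-lumen phantom --n 1 --difficulty easy --seed 7 --out cases/
ivoct-lumen segment cases/case000.png --gold cases/case000_gold.png --out results/
ivoct-lumen evaluate results/case000_mask.png cases/case000_gold.png
```

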