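# Methods

This note records the model behind `ivoct-lumen`, the parameters that
matter, the numerical conventions that had to be pinned, and what the
synthetic test bench does and does not establish.

## Problem and signal model

A display-format TD-OCT cross-section shows, from the centre outward: the
catheter reflection ring (bright, fixed, known maximum radius), the dark
blood-cleared lumen, the first tissue interface (the lumen border — the
segmentation target), and a bright wall band whose intensity decays
roughly exponentially with depth.  Three properties of the physics drive
the design:

* OCT cannot see behind the first strong interface, so everything
  radially deeper than the first tissue return can be treated as
  tissue-equivalent ("upward filling" in the polar domain).
* The near-infrared return depends on catheter-to-wall distance, so
  tissue/lumen contrast varies with angle.  Any global threshold fails on
  the far side of an eccentric catheter; a per-A-line threshold does not,
  because each A-line still contains exactly two intensity populations.
* Side-branch ostia return no signal at all, leaving an angular shadow
  sector with no lumen border to find.  These gaps must be detected and
  bridged, not segmented.

## Pipeline stages and parameters

| parameter | default | units | role |
|---|---|---|---|
| `r_max_px` (r_Max) | 30 | px | catheter-ring erase radius; also the adaptive closing diameter D |
| `median_window` | 5 | px | despeckle / alignment-mark attenuation |
| `n_r` × `n_theta` | 200 × 630 | samples | polar grid; 630 ≈ 0.57°/A-line |
| `se_small_diam_px` | 3 | px | polar opening element (speckle removal) |
| `gap_k` | 5.0 | – | gap threshold in SDs of the height derivative |
| `fov_mm` | 6.0 | mm | physical field of view; sets mm/px = fov/side |

The polar transform uses bilinear interpolation, angle 0 at east,
counter-clockwise, r = 0 at the catheter axis, and the radial scale chosen
so the last sample reaches the largest radius fully inside the frame; the
inverse transform uses the same conventions with the angle interpolated
circularly.  Both directions of the transform, and all morphology,
derivatives and interpolation in the polar domain, treat θ as circular.

The wavelet step is a single level of an *undecimated* (à-trous)
separable Daubechies-1 packet frame, so all four coefficient planes stay
pixel-aligned with the polar frame; the low-pass is normalised to an
averaging filter (DC-preserving) so the approximation plane cA1 keeps
intensity semantics for the Otsu stage.  Borders are edge-replicated.

Otsu thresholds are computed on a 256-bin histogram over each sample's own
min–max range; class means use exact per-bin intensity sums, so the
maximised between-class variance is exactly that of the empirical
partition, and ties (within 1e-9 relative) resolve to the lowest cut.
Foreground is strictly greater than the threshold.  A column whose range
is below 1e-6 of full scale carries no evidence and binarises to
background.

Disk structuring elements are discrete Euclidean disks (a pixel belongs to
the element iff its centre lies within the radius, radius = (d−1)/2 for
diameter d).  Erosions and dilations are computed through exact Euclidean
distance transforms, which is mathematically identical to the footprint
formulation and fast for the large adaptive elements (D = r_Max for the
polar closing, R_min = minimum lumen radius, floored at 3 px, for the
final Cartesian opening).

## Gap detection and correction

The boundary height h(θ) (first tissue row per column; n_r for an empty
column) is differentiated circularly and thresholded at
T = `gap_k` · SD(d), with the SD taken over the full derivative signal,
gap columns included.  In practice a shadow sector binarises
all-foreground — the only contrast left in such an A-line is the zeroed
catheter-erase disk against the noisy background — so real gaps pull h
down toward the catheter, while synthetic stress signals may push h up to
n_r; both orientations are handled identically.

The pairing of threshold crossings into intervals was a genuinely open
design point: a naive "open at one crossing, close at the next
opposite-sign crossing" state machine loses phase whenever a gap shoulder
splits into two same-direction above-threshold steps, after which every
interval is the complement of a gap.  The implemented rule therefore
classifies the *arcs between crossings*: an arc is part of a gap iff its
median height deviates from the global median by more than
max(T, 5 rows), and adjacent anomalous arcs merge.  Every emitted
interval is still delimited by a crossing and the next opposite-sign
crossing; the classification only fixes the phase.  The 5-row floor stops
±1-row quantisation staircases from being flagged when the overall
derivative SD is tiny.

Correction deletes the gap columns plus a 2-column guard band on each
side (the adaptive closing rounds gap shoulders), then interpolates the
surviving samples with a monotone piecewise cubic Hermite (PCHIP) scheme
on the circularly unwrapped index axis.  One circular fit over all
support columns is used; since PCHIP node derivatives depend only on
adjacent slopes, this equals independent per-gap correction for disjoint
gaps.  Interpolated values are rounded and clipped to [0, n_r − 1].

## Phantom generator

The generator renders, per frame: an analytic lumen boundary
ρ(θ) = R·(1 + e·cos(θ − φ)) + A·sin(fθ) (the gold mask is its exact
rasterisation); a wall whose intensity is
I_tissue · gain(θ) · exp(−μ·depth) with a darker layer beyond the bright
band; unit-mean gamma-distributed multiplicative speckle of chosen
contrast; additive detector noise; the catheter ring and an alignment-mark
ray; optional dim Gaussian intraluminal blobs (partially flushed blood);
and branch sectors in which the wall term is suppressed to background.
Defaults: 400 px / 6 mm frames, lumen radius 1.1–1.8 mm, catheter ring at
28 px (inside the 30-px erase radius), attenuation 2 mm⁻¹, speckle
contrast 0.25–0.35 ("easy") or 0.4–0.55 ("hard"), angular gain floor 0.2
and one or two 10–35° branch sectors on the hard suite — values chosen to
look like typical coronary TD-OCT frames.

What the phantoms do **not** emulate: real speckle correlation length and
texture, stent struts, non-circular catheter position (the generator and
pipeline both assume a centred catheter), layered plaque morphology, and
scan-conversion artefacts.  Passing the synthetic suites therefore shows
that the geometry, contrast-invariance and gap machinery work as designed,
not that clinical-grade accuracy transfers to any particular scanner.

## Numerical and degenerate-input conventions

* Masks are boolean; "foreground" is the object named by the variable
  (tissue in cA1_bin and l_polar*, lumen in lumen_bin).
* `polar_reconstruct` refuses all-background input ("no tissue
  detected"); `cartesian_reconstruct` refuses an all-foreground polar
  object ("lumen not found"); an empty segmentation makes the maximum
  false-negative deviation undefined and raises rather than reporting 0.
* The final component selection keeps the Cartesian component containing
  the catheter axis, falling back to the nearest component.
* Contours are marching-squares polylines at level 0.5; closed contours
  are smoothed with a 5-point circular moving average of the vertices,
  which removes the pixel-staircase length bias of the raw polyline.
* The pipeline contains no randomness: identical frame + configuration
  gives byte-identical masks.

## Problem sizes used by the test bench

The standard suites are 20 easy and 20 hard phantoms at 400 px / 6 mm,
segmented at the 200 × 630 polar grid — a size at which a full
segmentation takes a fraction of a second, so suites of this size
characterise mean behaviour while keeping the whole bench interactive.

## Known limitations

* r_Max is a configuration parameter, not auto-detected; frames whose
  catheter ring exceeds it will leak ring pixels into the features.
* A branch shadow wider than ~180° leaves too little support for the
  interpolation and the correction degrades gracefully but inaccurately.
* When two branch sectors split the wall into two arcs, the largest-arc
  selection discards the smaller arc and the correction interpolates
  across both sectors and the lost arc; accuracy drops a few Dice points
  on such frames.
* The method is tuned to TD-OCT texture; FD-OCT frames have different
  speckle statistics and would need the feature stage revisited.
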