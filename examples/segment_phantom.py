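"""Segment one synthetic frame and score it against its gold mask.

Builds a moderately noisy phantom (speckle, angular contrast loss, two dim
intraluminal blobs), runs the full pipeline, and prints the seven-value
accuracy panel.  TP/FP/FN are percent of the gold lumen area, the Max
deviations are worst-case boundary errors in millimetres, OR/OD are
Jaccard and Dice in percent.
"""

from ivoct_lumen import (
    PhantomParams, evaluate_masks, generate_phantom, run_pipeline,
)

img, gold, meta = generate_phantom(
    PhantomParams(seed=3, gain_min=0.7, speckle_contrast=0.3, blob_count=2)
)
lumen, contour, report = run_pipeline(img)
metrics = evaluate_masks(lumen, gold, fov_mm=img.fov_mm)

print(f"lumen area: {int(lumen.pixels.sum())} px "
      f"(gold {meta['lumen_area_px']} px)")
for key, value in metrics.as_dict().items():
    print(f"  {key:10s} {value:8.3f}")
print("A TP near 100 % with Max deviations well under 0.1 mm means the "
      "traced border stays within a pixel or two of the true lumen wall.")
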