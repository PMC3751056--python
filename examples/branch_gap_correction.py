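"""Effect of branch-shadow gap correction on a bifurcation frame.

A side-branch ostium leaves an angular sector with no wall return.  The
script renders such a frame, segments it with gap correction on and off,
and prints the detected gap interval (in polar columns, 630 per turn)
against the true shadow sector recorded by the generator.
"""

from ivoct_lumen import (
    PhantomParams, PipelineConfig, evaluate_masks, generate_phantom,
    run_pipeline,
)

img, gold, meta = generate_phantom(PhantomParams(
    seed=5, gain_min=0.2, speckle_contrast=0.5,
    branch_sectors=((80.0, 25.0),), blob_count=3, blob_intensity=0.3,
))

lumen_on, _, report = run_pipeline(img)
lumen_off, _, _ = run_pipeline(img, PipelineConfig(gap_correction=False))

print(f"true branch columns:     {meta['branch_cols']}")
print(f"detected gap intervals:  "
      f"{[(g['start'], g['end']) for g in report.gaps]}")
d_on = evaluate_masks(lumen_on, gold, fov_mm=img.fov_mm).od_pct
d_off = evaluate_masks(lumen_off, gold, fov_mm=img.fov_mm).od_pct
print(f"Dice with correction:    {d_on:6.2f} %")
print(f"Dice without correction: {d_off:6.2f} %")
print("Without correction the lumen border collapses to the catheter "
      "radius inside the shadow; interpolating the boundary height across "
      "the detected interval restores it.")
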