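"""Show that segmentation is invariant to global illumination changes.

The same scene is processed at full lamp brightness and dimmed to 70%.
Because every color cue the pipeline uses lives in chromaticity space
(channel fractions, not absolute intensities), the segmentations agree
almost pixel-for-pixel.
"""

from wbcseg import (
    RunConfig,
    SceneSpec,
    SegmentationParams,
    apply_illumination,
    make_smear,
    segment_image,
)
from wbcseg.evaluate import match_regions

params = SegmentationParams(resize_factor=1.0)
image, truth = make_smear(SceneSpec(n_wbc=5, n_rbc=20, seed=42))
dimmed = apply_illumination(image, 0.7)

res_full = segment_image(image, RunConfig(params=params))
res_dim = segment_image(dimmed, RunConfig(params=params))

print(f"cells at illumination 1.0: {res_full.n_cells}")
print(f"cells at illumination 0.7: {res_dim.n_cells}")

assignment = match_regions(res_dim.wbc_labels, res_full.wbc_labels, 0.5)
print("per-cell overlap between the two runs (IoU):")
for t, p, iou in assignment.matches:
    print(f"  cell {t}: {iou:.3f}")
print("An IoU near 1.0 for every cell means the dimmed image produced "
      "essentially the same footprints — the rg-chromaticity front end "
      "cancels the multiplicative intensity change.")
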