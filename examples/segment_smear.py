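"""Segment one synthetic blood smear and report per-cell morphology.

Builds a peripheral-blood-like scene (5 WBCs among red cells), runs the
full four-phase pipeline, and prints each detected cell's area, roundness
and how it was obtained, plus the cell-level agreement with the ground
truth.
"""

from wbcseg import (
    RunConfig,
    SceneSpec,
    SegmentationParams,
    evaluate_masks,
    make_smear,
    segment_image,
)

# synthetic scenes are generated directly at working resolution, so the
# pipeline's 0.2x resize is disabled
params = SegmentationParams.for_smear("peripheral").replace(resize_factor=1.0)
spec = SceneSpec(n_wbc=5, n_rbc=25, seed=7, lobes_per_nucleus=(1, 3))

image, truth = make_smear(spec)
result = segment_image(image, RunConfig(params=params))

print(f"detected {result.n_cells} white blood cells "
      f"(ground truth: {truth.n_cells})\n")
print(f"{'label':>5} {'area':>6} {'roundness':>9} {'origin':>12}")
for p in result.props:
    print(f"{p.label:>5} {p.area:>6} {p.roundness:>9.2f} "
          f"{result.provenance.get(p.label, 'single'):>12}")

report = evaluate_masks(result.wbc_labels, truth.wbc_labels, 0.5)
print(f"\ncell-level agreement at IoU 0.5: TP={report.tp} FP={report.fp} "
      f"FN={report.fn}  F1={report.f1:.3f}")
print("Areas in the 460-3367 px working-scale band are typical of single "
      "cells; 'origin' shows whether the watershed had to split the region "
      "out of a clump.")
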