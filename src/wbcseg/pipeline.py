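"""End-to-end orchestration: resize → Phase I → II → III/IV → post-process.

The raw micrograph is downscaled by ``resize_factor`` (default 0.2, the
scale at which every pixel threshold is calibrated), the four phases run at
that working resolution, and the final label masks are mapped back to the
original resolution by nearest-neighbor upsampling.  The whole pipeline is
deterministic: identical input and configuration give byte-identical
outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

from .evaluate import EvalReport, evaluate_masks, f_measure
from .nmwo import SegmentationResult, postprocess, separate_wbcs
from .params import RunConfig
from .seeds import build_inside_seeds
from .wbc_region import build_outside_seeds

__all__ = ["segment_image", "run_batch", "BatchSummary", "save_result",
           "overlay_contours"]

log = logging.getLogger("wbcseg")

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
TRUTH_SUFFIX = "_truth.png"


def _resize_rgb(image: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return image
    h = max(int(round(image.shape[0] * factor)), 16)
    w = max(int(round(image.shape[1] * factor)), 16)
    out = _sk_resize(image.astype(np.float64), (h, w, 3),
                     anti_aliasing=True, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _upsample_labels(labels: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if labels.shape == shape:
        return labels
    out = _sk_resize(labels, shape, order=0, anti_aliasing=False,
                     preserve_range=True)
    return out.astype(labels.dtype)


def _dump(debug_dir: Path | None, name: str, arr: np.ndarray) -> None:
    if debug_dir is None:
        return
    debug_dir.mkdir(parents=True, exist_ok=True)
    if arr.dtype == bool:
        arr = (arr * 255).astype(np.uint8)
    elif arr.dtype not in (np.uint8, np.uint16):
        arr = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
    iio.imwrite(debug_dir / f"{name}.png", arr)


def segment_image(image: np.ndarray, config: RunConfig) -> SegmentationResult:
    """Run the full four-phase segmentation on one RGB smear image.

    Returns label masks at the input resolution; region properties are
    measured at the working resolution where the thresholds live.
    """
    params = config.params
    t0 = time.perf_counter()
    work = _resize_rgb(image, params.resize_factor)
    log.info("working image %dx%d (resize %.2g)", work.shape[0],
             work.shape[1], params.resize_factor)

    seeds = build_inside_seeds(work, params)
    nucleus_area = int(seeds.nucleus_raw.sum())
    log.info("phase I: nucleus area %d px", nucleus_area)
    _dump(config.debug_dir, "nucleus_raw", seeds.nucleus_raw)
    _dump(config.debug_dir, "inside_seeds", seeds.inside)

    outside = build_outside_seeds(work, nucleus_area, params)
    seeds.outside = outside
    log.info("phase II: outside-seed area %d px", int(outside.sum()))
    _dump(config.debug_dir, "outside_seeds", outside)

    labels, provenance = separate_wbcs(outside, seeds.inside, params,
                                       return_provenance=True)
    log.info("phase III/IV: %d candidate regions", int(labels.max()))
    result = postprocess(labels, seeds.nucleus_raw, provenance)
    log.info("post-processing: %d cells kept (%.2fs total)",
             result.n_cells, time.perf_counter() - t0)
    _dump(config.debug_dir, "wbc_labels", result.wbc_labels.astype(np.uint16))

    result.wbc_labels = _upsample_labels(result.wbc_labels, image.shape[:2])
    result.nucleus_labels = _upsample_labels(result.nucleus_labels,
                                             image.shape[:2])
    return result


def overlay_contours(image: np.ndarray, labels: np.ndarray,
                     color: tuple[int, int, int] = (255, 0, 0)) -> np.ndarray:
    """Input image with cell boundaries drawn in red."""
    from skimage.segmentation import find_boundaries

    out = np.asarray(image).copy()
    edges = find_boundaries(labels, mode="outer")
    out[edges] = color
    return out


def save_result(result: SegmentationResult, out_dir: str | Path,
                stem: str, image: np.ndarray | None = None,
                overlay: bool = False) -> None:
    """Write label masks (16-bit PNG), a per-cell CSV and optional overlay."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_dir / f"{stem}_wbc.png",
                result.wbc_labels.astype(np.uint16))
    iio.imwrite(out_dir / f"{stem}_nucleus.png",
                result.nucleus_labels.astype(np.uint16))
    rows = [{"label": p.label, "area": p.area, "perimeter": p.perimeter,
             "height": p.height, "width": p.width, "roundness": p.roundness,
             "cx": p.centroid[0], "cy": p.centroid[1],
             "provenance": result.provenance.get(p.label, "single")}
            for p in result.props]
    pd.DataFrame(rows).to_csv(out_dir / f"{stem}_cells.csv", index=False)
    if overlay and image is not None:
        iio.imwrite(out_dir / f"{stem}_overlay.png",
                    overlay_contours(image, result.wbc_labels))


@dataclass
class BatchSummary:
    """Per-image results plus the aggregate counting report."""

    per_image: dict[str, SegmentationResult] = field(default_factory=dict)
    reports: dict[str, EvalReport] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    aggregate: EvalReport | None = None

    def aggregate_counts(self) -> None:
        if not self.reports:
            self.aggregate = None
            return
        tp = sum(r.tp for r in self.reports.values())
        fp = sum(r.fp for r in self.reports.values())
        fn = sum(r.fn for r in self.reports.values())
        precision, recall, f1 = f_measure(tp, fp, fn)
        self.aggregate = EvalReport(
            tp=tp, fp=fp, fn=fn,
            overseg=sum(r.overseg for r in self.reports.values()),
            underseg=sum(r.underseg for r in self.reports.values()),
            precision=precision, recall=recall, f1=f1)


def run_batch(input_dir: str | Path, config: RunConfig,
              out_dir: str | Path | None = None) -> BatchSummary:
    """Segment every image in a directory, in sorted (reproducible) order.

    An image ``x.png`` with a sibling ``x_truth.png`` 16-bit label mask is
    also evaluated against that truth; the aggregate report sums the
    counts.  Per-image failures are logged and recorded, not raised.
    """
    input_dir = Path(input_dir)
    summary = BatchSummary()
    images = sorted(p for p in input_dir.iterdir()
                    if p.suffix.lower() in IMAGE_SUFFIXES
                    and not p.name.endswith(TRUTH_SUFFIX)
                    and "_wbc" not in p.name and "_nucleus" not in p.name)
    if not images:
        log.warning("no images found in %s", input_dir)
        return summary
    for path in images:
        try:
            image = iio.imread(path)
            if image.ndim == 3 and image.shape[2] == 4:
                image = image[..., :3]
            result = segment_image(image, config)
        except Exception as exc:  # noqa: BLE001 - batch must continue
            log.error("failed on %s: %s", path.name, exc)
            summary.failures[path.name] = str(exc)
            continue
        summary.per_image[path.name] = result
        if out_dir is not None:
            save_result(result, out_dir, path.stem, image=image,
                        overlay=config.overlay)
        truth_path = path.with_name(path.stem + TRUTH_SUFFIX)
        if truth_path.exists():
            truth = iio.imread(truth_path).astype(np.int32)
            summary.reports[path.name] = evaluate_masks(
                result.wbc_labels, truth, config.params.iou_match)
    summary.aggregate_counts()
    return summary
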