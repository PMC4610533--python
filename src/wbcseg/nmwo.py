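"""Phases III–IV — nucleus-marked watershed separation of adhesive cells.

A clump of overlapping WBCs shows up as one large, irregular component of
the outside-seed mask: its area exceeds S3 and its compactness roundness
exceeds R, neither of which a single round cell can reach.  Such components
are split by watershed flooding of the negated distance-to-background
surface, seeded at the nucleus groups (one marker per cell when Phase I
succeeded).  Regions still adhesive afterwards — typically because two
nuclei merged into one seed — go through a second, marker-free pass that
derives seeds from the distance transform itself (plateaus deeper than Rs)
or, failing that, from iterative erosion until the clump falls apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed as _sk_watershed

from .morphology import (
    RegionProps,
    binary_erode,
    connected_components,
    denoise_small,
    region_props,
    relabel_consecutive,
)
from .params import SegmentationParams

# erosion cores below the minimum nucleus area cannot be cell cores; ragged
# boundaries shed slivers under erosion that would otherwise seed spurious
# basins.  Distance-transform plateaus are smooth, so a smaller floor
# suffices to reject noise there while keeping genuine small cores.
MIN_CORE_AREA = 100
MIN_PLATEAU_AREA = 30

__all__ = [
    "SegmentationResult",
    "detect_adhesion",
    "marked_watershed",
    "adaptive_split",
    "separate_wbcs",
    "postprocess",
]


@dataclass
class SegmentationResult:
    """Final per-cell segmentation.

    ``provenance`` maps each WBC label to how it was obtained: ``single``
    (never split), ``split_pass1`` (nucleus-marked watershed) or
    ``split_pass2`` (adaptive distance/erosion watershed).
    """

    wbc_labels: np.ndarray
    nucleus_labels: np.ndarray
    props: list[RegionProps] = field(default_factory=list)
    provenance: dict[int, str] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(self.wbc_labels.max())


def detect_adhesion(props: RegionProps, params: SegmentationParams) -> bool:
    """A region is an adhesive clump iff area > S3 and roundness > R.

    The roundness comparator is configurable; the default follows the
    parameter-calibration convention (merged clumps are less compact, so
    their perimeter²/(4πA) roundness is *higher*).
    """
    if props.area <= params.S3:
        return False
    if params.adhesion_roundness_cmp == "gt":
        return props.roundness > params.R
    return props.roundness < params.R


def marked_watershed(outside: np.ndarray, markers: np.ndarray,
                     surface: str = "dist_to_bg") -> np.ndarray:
    """Marker-controlled watershed of a binary mask.

    The topographic surface is the negated Euclidean distance to the
    background (``dist_to_bg``, the standard construction: basins are
    deepest at cell centers) or the distance to the nearest seed
    (``dist_to_seed``).  Flooding is restricted to ``outside``; every
    foreground pixel ends up in exactly one basin, so the output labels
    partition the mask.
    """
    outside = np.asarray(outside).astype(bool)
    markers = np.asarray(markers)
    if markers.shape != outside.shape:
        raise ValueError("marker/mask shape mismatch")
    markers = np.where(outside, markers, 0).astype(np.int32)
    if markers.max() == 0:
        raise ValueError("no markers inside the mask")
    if surface == "dist_to_bg":
        height = -ndi.distance_transform_edt(outside)
    elif surface == "dist_to_seed":
        height = ndi.distance_transform_edt(markers == 0)
    else:
        raise ValueError(f"unknown surface {surface!r}")
    return _sk_watershed(height, markers=markers, mask=outside,
                         connectivity=1).astype(np.int32)


def adaptive_split(region: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Second-pass split of one adhesive component without nucleus markers.

    Markers are the connected plateaus where the distance-to-background
    transform is at least Rs (each cell core in a clump is deeper than Rs).
    If fewer than two such plateaus exist, the region is eroded by a
    radius-1 disk per step until its component count increases (those
    components become the markers) or the next erosion would empty it, in
    which case the region is returned unsplit as a single label.

    Marker candidates below a minimum area are ignored (MIN_PLATEAU_AREA
    for distance plateaus, MIN_CORE_AREA for erosion cores): ragged
    boundaries shed small slivers under erosion, and a sliver marker would
    carve a spurious cell out of the clump.
    """
    region = np.asarray(region).astype(bool)
    dist = ndi.distance_transform_edt(region)
    plateaus = denoise_small(dist >= params.Rs, MIN_PLATEAU_AREA)
    markers = connected_components(plateaus, connectivity=4)
    if markers.max() < 2:
        cur = region
        markers = None
        while True:
            eroded = binary_erode(cur, 1)
            if not eroded.any():
                return region.astype(np.int32)  # unsplittable
            cores = denoise_small(eroded, MIN_CORE_AREA)
            comps = connected_components(cores, connectivity=4)
            if comps.max() > 1:
                markers = comps
                break
            if not cores.any():
                return region.astype(np.int32)  # only slivers left
            cur = eroded
    return marked_watershed(region, markers,
                            surface=params.watershed_surface)


def separate_wbcs(outside: np.ndarray, inside: np.ndarray,
                  params: SegmentationParams,
                  return_provenance: bool = False):
    """NMWO: separate adhesive WBC clumps using nucleus-group markers.

    Pass 1 splits every adhesive component of ``outside`` by watershed
    seeded at the inside-seed components it contains (skipped when fewer
    than two seeds fall inside).  Components still adhesive afterwards go
    through :func:`adaptive_split`.  Non-adhesive components pass through
    untouched — including seedless ones, which post-processing removes.
    Labels are compacted to 1..K in raster order.

    ``inside`` may be a boolean mask (each connected component becomes one
    marker, the pipeline case where lobes were already centroid-connected)
    or an integer label mask whose labels group nucleus parts per cell.
    """
    outside = np.asarray(outside).astype(bool)
    inside = np.asarray(inside)
    if outside.shape != inside.shape:
        raise ValueError("outside/inside shape mismatch")

    comp = connected_components(outside, connectivity=4)
    props = region_props(comp)
    if inside.dtype == bool:
        inside_labels = connected_components(inside & outside, connectivity=4)
    else:
        inside_labels = np.where(outside, inside, 0).astype(np.int32)

    next_label = 1
    out = np.zeros(outside.shape, dtype=np.int32)
    prov: dict[int, str] = {}

    def emit(mask: np.ndarray, how: str) -> None:
        nonlocal next_label
        out[mask] = next_label
        prov[next_label] = how
        next_label += 1

    for p in props:
        cmask = comp == p.label
        if not detect_adhesion(p, params):
            emit(cmask, "single")
            continue
        # pass 1: nucleus-marked watershed (needs at least two seeds)
        seeds = np.where(cmask, inside_labels, 0)
        n_seeds = len(np.unique(seeds)) - 1
        if n_seeds >= 2:
            pieces = marked_watershed(cmask, seeds,
                                      surface=params.watershed_surface)
            how = "split_pass1"
        else:
            pieces, how = cmask.astype(np.int32), "single"
        # pass 2: re-test each piece, adaptive split where still adhesive
        pieces = relabel_consecutive(pieces)
        for q in region_props(pieces):
            pmask = pieces == q.label
            if detect_adhesion(q, params):
                sub = adaptive_split(pmask, params)
                n_sub = int(sub.max())
                for lbl in range(1, n_sub + 1):
                    emit(sub == lbl, "split_pass2" if n_sub > 1 else how)
            else:
                emit(pmask, how)

    compacted = relabel_consecutive(out)
    if not return_provenance:
        return compacted
    # compaction permutes ids; recover each new id's origin via any pixel
    prov_out: dict[int, str] = {}
    for new in range(1, int(compacted.max()) + 1):
        ys, xs = np.nonzero(compacted == new)
        prov_out[new] = prov[int(out[ys[0], xs[0]])]
    return compacted, prov_out


def postprocess(wbcs: np.ndarray, nucleus: np.ndarray,
                provenance: dict[int, str] | None = None) -> SegmentationResult:
    """Final cleanup: assign nuclei to cells and drop nucleus-free debris.

    The logical AND of the separated-WBC labels with the nucleus mask both
    assigns each nucleus its cell's label and splits adhesive nuclei along
    the watershed ridge.  WBC components containing no nucleus pixel are
    impurities (stain debris, stray red cells picked up by Phase II) and
    are removed — this is morphological reconstruction of the WBC mask from
    the nucleus marker, expressed on labels.
    """
    wbcs = np.asarray(wbcs)
    nucleus = np.asarray(nucleus).astype(bool)
    if wbcs.shape != nucleus.shape:
        raise ValueError("shape mismatch")
    k = int(wbcs.max())
    keep = np.zeros(k + 1, dtype=bool)
    hit = np.unique(wbcs[nucleus])
    keep[hit[hit > 0]] = True
    kept = np.where(keep[wbcs], wbcs, 0)
    out = relabel_consecutive(kept)
    nucleus_labels = np.where(nucleus, out, 0)
    props = region_props(out)
    prov_out: dict[int, str] = {}
    if provenance is not None:
        # relabel_consecutive orders by first raster pixel, which the emit
        # order does not guarantee; rebuild by pixel lookup
        for new in range(1, int(out.max()) + 1):
            ys, xs = np.nonzero(out == new)
            prov_out[new] = provenance.get(int(wbcs[ys[0], xs[0]]), "single")
    return SegmentationResult(wbc_labels=out, nucleus_labels=nucleus_labels,
                              props=props, provenance=prov_out)
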