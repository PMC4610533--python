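"""Binary morphology toolbox shared by all pipeline phases.

Connected components use 4-connectivity by default, matching the denoising
convention used to calibrate the area thresholds.  Region perimeters are
measured by tracing the outer boundary as an 8-directional chain code with
axis steps weighted 1 and diagonal steps weighted √2; roundness is the
compactness perimeter²/(4π·area), which is ≈1 for a digital disk and grows
with irregularity — merged cell clumps score well above single round cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as _sk_label
from skimage.morphology import dilation as _sk_dilate
from skimage.morphology import disk as _disk
from skimage.morphology import erosion as _sk_erode

__all__ = [
    "RegionProps",
    "connected_components",
    "denoise_small",
    "reconstruct",
    "region_props",
    "binary_erode",
    "binary_dilate",
    "relabel_consecutive",
]

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class RegionProps:
    """Morphological descriptors of one labeled region.

    ``centroid`` is (x, y) = (col, row) in 0-based pixel-center coordinates.
    """

    label: int
    area: int
    perimeter: float
    height: int
    width: int
    roundness: float
    centroid: tuple[float, float]


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return mask.astype(bool)


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Compact positive labels to 1..K in raster order of first pixel."""
    labels = np.asarray(labels)
    out = np.zeros_like(labels, dtype=np.int32)
    flat = labels.ravel()
    pos = flat > 0
    if not pos.any():
        return out
    idx = np.flatnonzero(pos)
    # first flat index of each label decides its rank
    maxlab = int(flat.max())
    first = np.full(maxlab + 1, flat.size, dtype=np.int64)
    np.minimum.at(first, flat[idx], idx)
    present = np.flatnonzero(first < flat.size)
    order = present[np.argsort(first[present], kind="stable")]
    remap = np.zeros(maxlab + 1, dtype=np.int32)
    remap[order] = np.arange(1, len(order) + 1, dtype=np.int32)
    out.ravel()[idx] = remap[flat[idx]]
    return out


def connected_components(mask: np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Label connected foreground sets 1..K, raster-ordered by first pixel."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    m = _as_bool(mask)
    lab = _sk_label(m, connectivity=1 if connectivity == 4 else 2)
    return relabel_consecutive(lab)


def denoise_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 4-connected components with area strictly below ``min_area``."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    m = _as_bool(mask)
    if min_area <= 1 or not m.any():
        return m.copy()
    lab, k = ndi.label(m, structure=ndi.generate_binary_structure(2, 1))
    if k == 0:
        return m.copy()
    areas = np.bincount(lab.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[lab]


def reconstruct(marker: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Binary morphological reconstruction of ``mask`` from ``marker``.

    Returns the union of the 4-connected components of ``mask`` that
    intersect ``marker``; markers overhanging the mask are clipped first.
    Equivalent to iterated conditional dilation to stability.
    """
    mk = _as_bool(marker)
    ms = _as_bool(mask)
    if mk.shape != ms.shape:
        raise ValueError("marker/mask shape mismatch")
    mk = mk & ms
    if not mk.any():
        return np.zeros_like(ms)
    lab, k = ndi.label(ms, structure=ndi.generate_binary_structure(2, 1))
    hit = np.unique(lab[mk])
    hit = hit[hit > 0]
    keep = np.zeros(k + 1, dtype=bool)
    keep[hit] = True
    return keep[lab]


def binary_erode(mask: np.ndarray, radius: int) -> np.ndarray:
    """Erosion by a disk structuring element."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return _sk_erode(_as_bool(mask), _disk(radius))


def binary_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Dilation by a disk structuring element."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return _sk_dilate(_as_bool(mask), _disk(radius))


# clockwise Moore neighborhood starting due north, (drow, dcol)
_NB8 = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_STEP_LEN = tuple(SQRT2 if dr and dc else 1.0 for dr, dc in _NB8)


_DIR_INDEX = {d: i for i, d in enumerate(_NB8)}


def chain_code_perimeter(region: np.ndarray) -> float:
    """Length of the outer boundary chain code of a single connected region.

    Moore-neighbor tracing (clockwise, starting from the uppermost-leftmost
    pixel) with the stop-on-repeated-first-move criterion; axis steps count
    1, diagonal steps √2.  A single-pixel region has an empty chain and
    takes perimeter 1 so downstream ratios stay finite.
    """
    m = np.pad(_as_bool(region), 1)
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        return 0.0
    start = (int(rows[0]), int(cols[0]))  # uppermost-leftmost
    cur = start
    back = (start[0], start[1] - 1)  # due west, guaranteed background
    perim = 0.0
    first_move = None
    while True:
        db = _DIR_INDEX[(back[0] - cur[0], back[1] - cur[1])]
        found = -1
        for s in range(1, 9):
            d = (db + s) % 8
            cand = (cur[0] + _NB8[d][0], cur[1] + _NB8[d][1])
            if m[cand]:
                found = d
                break
            back = cand  # remember last background probed
        if found < 0:
            return 1.0  # isolated pixel
        if first_move is None:
            first_move = (cur, found)
        elif (cur, found) == first_move:
            break  # tour closed: about to repeat the initial move
        perim += _STEP_LEN[found]
        cur = cand
        if perim > 8.0 * m.size:  # safety net, never hit on valid masks
            raise RuntimeError("boundary trace failed to close")
    return perim if perim > 0 else 1.0


def region_props(labels: np.ndarray) -> list[RegionProps]:
    """Chain-code region properties for every positive label."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("labels must be 2-D")
    out: list[RegionProps] = []
    if labels.size == 0 or labels.max() <= 0:
        return out
    slices = ndi.find_objects(labels)
    for i, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        crop = labels[sl] == i
        area = int(crop.sum())
        perim = chain_code_perimeter(crop)
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        rr, cc = np.nonzero(crop)
        cy = float(rr.mean() + sl[0].start)
        cx = float(cc.mean() + sl[1].start)
        roundness = perim * perim / (4.0 * math.pi * area)
        out.append(RegionProps(label=i, area=area, perimeter=perim,
                               height=h, width=w, roundness=roundness,
                               centroid=(cx, cy)))
    return out
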