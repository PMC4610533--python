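"""Phase I — nucleus extraction and inside seeds.

The stained nucleus is simultaneously the most saturated structure in the
smear and the one poorest in green chromaticity, so the ratio image
``IE = Is / Ig`` (both planes min-max normalized to bytes) is ≫ 1 on nuclei
and < 1 on red cells and background.  Otsu thresholding of IE, followed by
small-component denoising, yields the nucleus mask.

Multi-lobed nuclei (segmented neutrophils) would contribute several seeds
for one cell; the centroid-connected operation merges lobe pairs whose
areas fall in the single-lobe range (s11, s12) and whose minimum mutual
distance is below l11, by painting a T2-padded axis-aligned rectangle
spanning the two centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .color import (
    normalize_plane,
    ratio_enhance,
    rgb_to_hsi_saturation,
    rgb_to_rg_chroma,
)
from .morphology import connected_components, denoise_small, region_props
from .params import SegmentationParams

__all__ = [
    "SeedSet",
    "CorePair",
    "otsu_threshold",
    "segment_nucleus",
    "find_multi_cores",
    "centroid_connect",
    "build_inside_seeds",
]

# percentile of the IE ratio over nucleus-candidate pixels used as the
# byte-scale ceiling.  The raw ratio is unbounded where normalized Ig
# approaches zero inside the nucleus; anchoring the ceiling at the lower
# quartile of the candidates saturates the candidate class into the top
# histogram bins, so Otsu separates it from the background instead of
# splitting the candidates' own heavy tail.
IE_CAP_PERCENTILE = 25.0


@dataclass
class SeedSet:
    """Masks produced by Phases I–II.

    ``inside`` marks nucleus groups (one component per cell, ideally),
    ``nucleus_raw`` is the pre-connection nucleus mask, ``outside`` the full
    WBC-region mask (filled by Phase II, empty until then).
    """

    inside: np.ndarray
    nucleus_raw: np.ndarray
    outside: np.ndarray | None = None


@dataclass(frozen=True)
class CorePair:
    """Two nucleus lobes eligible for centroid connection."""

    label_a: int
    label_b: int
    centroid_a: tuple[float, float]  # (x, y)
    centroid_b: tuple[float, float]
    distance: float  # minimum boundary-to-boundary distance


def otsu_threshold(plane: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram of a byte-scaled plane.

    Exhaustively scans all candidate thresholds and returns the gray level
    maximizing the between-class variance, breaking ties toward the
    smallest threshold.  A constant plane is degenerate: its value is
    returned with a warning, so "strictly above" masks come out empty.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.size == 0:
        raise ValueError("empty plane")
    if plane.min() == plane.max():
        warnings.warn("constant plane passed to Otsu; foreground will be empty",
                      stacklevel=2)
        return float(plane.flat[0])
    hist, _ = np.histogram(plane, bins=256, range=(0.0, 255.0))
    hist = hist.astype(np.float64)
    total = hist.sum()
    omega = np.cumsum(hist) / total                # class-0 mass at t = 0..255
    mu = np.cumsum(hist * np.arange(256)) / total  # partial mean
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    return float(np.argmax(sigma_b))  # argmax takes the first (smallest) tie


def segment_nucleus(image: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Nucleus binary mask: Otsu on the enhancement ratio, then denoising.

    The enhancement IE is the ratio of the min-max-normalized saturation
    and g-chromaticity planes; Otsu keeps the high side and S1 denoising
    removes platelets and specks.  Because the normalization is anchored by
    whatever happens to span the extremes, the result is additionally
    gated by the scale-free separation property that defines a stained
    nucleus in the first place — raw saturation exceeding raw green
    chromaticity (S/g > 1); red cells and background satisfy the reverse
    inequality.  Without the gate, a smear with no (or a tiny) nucleus
    would promote red cells into the role of the normalization anchor.
    """
    chroma = rgb_to_rg_chroma(image)
    sat = rgb_to_hsi_saturation(image)
    gate = sat > chroma[..., 1]
    if not gate.any():
        return np.zeros(gate.shape, dtype=bool)
    ig = normalize_plane(chroma[..., 1])
    isat = normalize_plane(sat)
    ie = ratio_enhance(isat, ig)
    cap = float(np.percentile(ie[gate], IE_CAP_PERCENTILE))
    if cap <= 0:
        cap = float(ie.max()) or 1.0
    ie = normalize_plane(np.minimum(ie, cap))
    t = otsu_threshold(ie)
    mask = (ie > t) & gate
    return denoise_small(mask, params.S1)


def find_multi_cores(nucleus: np.ndarray, params: SegmentationParams) -> list[CorePair]:
    """All lobe pairs satisfying the multi-core geometry test.

    Both areas must lie strictly inside (s11, s12) and the minimum
    boundary-to-boundary distance must be below l11.  Pairs are returned
    sorted by increasing distance.
    """
    labels = connected_components(nucleus, connectivity=4)
    props = region_props(labels)
    cand = [p for p in props if params.s11 < p.area < params.s12]
    pairs: list[CorePair] = []
    for i in range(len(cand)):
        mask_i = labels == cand[i].label
        dist_i = ndi.distance_transform_edt(~mask_i)
        for j in range(i + 1, len(cand)):
            mask_j = labels == cand[j].label
            d = float(dist_i[mask_j].min())
            if d < params.l11:
                pairs.append(CorePair(cand[i].label, cand[j].label,
                                      cand[i].centroid, cand[j].centroid, d))
    pairs.sort(key=lambda p: p.distance)
    return pairs


def centroid_connect(nucleus: np.ndarray, pair: CorePair,
                     params: SegmentationParams) -> np.ndarray:
    """Merge one lobe pair by painting the T2-padded centroid rectangle.

    With centroids (x1, y1), (x2, y2), the filled rectangle spans
    x ∈ [max(min(x)−T2, 0), min(max(x)+T2, W−1)] and likewise in y, both
    corners inclusive (x = column, y = row).
    """
    nucleus = np.asarray(nucleus).astype(bool)
    h, w = nucleus.shape
    t2 = params.T2
    (x1, y1), (x2, y2) = pair.centroid_a, pair.centroid_b
    a = max(int(round(min(x1, x2))) - t2, 0)
    b = min(int(round(max(x1, x2))) + t2, w - 1)
    c = max(int(round(min(y1, y2))) - t2, 0)
    d = min(int(round(max(y1, y2))) + t2, h - 1)
    out = nucleus.copy()
    out[c:d + 1, a:b + 1] = True
    return out


def build_inside_seeds(image: np.ndarray, params: SegmentationParams) -> SeedSet:
    """Phase I end-to-end: nucleus mask, then lobe connection to fixed point.

    Pairs are reconnected smallest-distance first, recomputing eligibility
    after each merge (a merged group usually leaves the single-lobe area
    range, which is what terminates the loop).
    """
    nucleus_raw = segment_nucleus(image, params)
    inside = nucleus_raw.copy()
    # each connection removes at least one component, bounding the loop
    max_rounds = int(connected_components(inside, 4).max())
    for _ in range(max_rounds):
        pairs = find_multi_cores(inside, params)
        if not pairs:
            break
        inside = centroid_connect(inside, pairs[0], params)
    return SeedSet(inside=inside, nucleus_raw=nucleus_raw)
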