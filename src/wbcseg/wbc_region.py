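"""Phase II — WBC regions (outside seeds).

Two complementary strategies detect the full cell (nucleus + cytoplasm):

1. **Mean-shift + cyan channel.**  The CMYK cyan fraction is high on the
   purple/blue stained WBC, low on red cells and background.  A joint
   spatial-intensity mean-shift filter smooths the plane into near-piecewise
   -constant regions, and an adaptive threshold anchored on the nucleus area
   cuts off the background.
2. **Chromaticity enhancement.**  WBC pixels have a higher blue-to-green
   chromaticity ratio than red cells or background; the ratio image
   ``Ien = b/g`` is thresholded by the same adaptive rule.

The adaptive rule assumes a WBC occupies about N times its nucleus's area
(N = 3 for peripheral blood, 1.5 for bone marrow): with total nucleus area
``Sn`` and image area ``Si``, the darkest ``Si − N·Sn`` pixels are declared
background and the threshold is the gray level where the cumulative
histogram reaches that budget.  The two binary masks are unioned, denoised
and hole-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage as ndi

from .color import normalize_plane, ratio_enhance, rgb_to_cmyk_c, rgb_to_rg_chroma
from .morphology import denoise_small
from .params import SegmentationParams

__all__ = [
    "MeanShiftConfig",
    "mean_shift_filter",
    "adaptive_threshold_fraction",
    "wbc_cluster_mask",
    "wbc_enhanced_mask",
    "build_outside_seeds",
]


@dataclass(frozen=True)
class MeanShiftConfig:
    """Bandwidths and stopping rule of the joint-domain mean shift."""

    hs: int = 3             # spatial Chebyshev bandwidth, pixels
    hr: float = 3.0         # intensity bandwidth, gray levels
    max_iters: int = 4
    convergence_tol: float = 0.5

    def __post_init__(self) -> None:
        if self.hs < 1:
            raise ValueError("hs must be >= 1")
        if self.hr <= 0:
            raise ValueError("hr must be > 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@njit(cache=True)
def _mean_shift_kernel(img, hs, hr, max_iters, tol):  # pragma: no cover
    h, w = img.shape
    out = np.empty((h, w), np.float64)
    for i in range(h):
        for j in range(w):
            py = float(i)
            px = float(j)
            pv = img[i, j]
            for _ in range(max_iters):
                y0 = int(np.ceil(py - hs))
                y1 = int(np.floor(py + hs))
                x0 = int(np.ceil(px - hs))
                x1 = int(np.floor(px + hs))
                if y0 < 0:
                    y0 = 0
                if y1 > h - 1:
                    y1 = h - 1
                if x0 < 0:
                    x0 = 0
                if x1 > w - 1:
                    x1 = w - 1
                sy = 0.0
                sx = 0.0
                sv = 0.0
                k = 0
                for yy in range(y0, y1 + 1):
                    for xx in range(x0, x1 + 1):
                        v = img[yy, xx]
                        if abs(v - pv) <= hr:
                            sy += yy
                            sx += xx
                            sv += v
                            k += 1
                if k == 0:
                    break
                nv = sv / k
                shift = abs(nv - pv)
                py = sy / k
                px = sx / k
                pv = nv
                if shift < tol:
                    break
            out[i, j] = pv
    return out


def mean_shift_filter(plane: np.ndarray,
                      config: MeanShiftConfig | None = None) -> np.ndarray:
    """Joint spatial-intensity mean-shift filtering with a flat kernel.

    Every pixel starts a mode search at its own (x, y, intensity) point.
    Each update replaces the estimate by the mean of all image samples
    lying within Chebyshev distance ``hs`` of the current spatial position
    and within ``hr`` of the current intensity; the search stops after
    ``max_iters`` updates or when the intensity moves less than
    ``convergence_tol``.  The output pixel takes the converged intensity,
    which stays inside the input intensity range (each update is a mean of
    input samples).
    """
    if config is None:
        config = MeanShiftConfig()
    plane = np.ascontiguousarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError("plane must be 2-D")
    return _mean_shift_kernel(plane, config.hs, float(config.hr),
                              config.max_iters, float(config.convergence_tol))


def adaptive_threshold_fraction(plane: np.ndarray, nucleus_area: float,
                                n_ratio: float) -> int:
    """Nucleus-area-anchored histogram threshold.

    The darkest ``Si − N·nucleus_area`` pixels (the red-cell + background
    budget) fall at or below the returned gray level; the foreground is
    everything strictly above it.  Returns the smallest gray level whose
    cumulative 256-bin histogram count reaches the budget.
    """
    plane = np.asarray(plane, dtype=np.float64)
    s_image = plane.size
    if s_image == 0:
        raise ValueError("empty plane")
    if nucleus_area < 0:
        raise ValueError("nucleus_area must be >= 0")
    target = s_image - n_ratio * nucleus_area
    if target < 0:
        warnings.warn("N * nucleus_area exceeds the image area; "
                      "thresholding at 0 keeps everything foreground",
                      stacklevel=2)
        return 0
    target = min(target, s_image)
    hist, _ = np.histogram(plane, bins=256, range=(0.0, 255.0))
    cum = np.cumsum(hist)
    idx = np.searchsorted(cum, target, side="left")
    return int(min(idx, 255))


def wbc_cluster_mask(image: np.ndarray, nucleus_area: float,
                     params: SegmentationParams) -> np.ndarray:
    """Strategy 1: mean-shift-filtered cyan channel, adaptive threshold."""
    c = normalize_plane(rgb_to_cmyk_c(image, naive=params.cmyk_naive))
    cfg = MeanShiftConfig(hs=params.hs, hr=params.hr,
                          max_iters=params.ms_max_iters,
                          convergence_tol=params.ms_convergence_tol)
    filtered = mean_shift_filter(c, cfg)
    t3 = adaptive_threshold_fraction(filtered, nucleus_area, params.N)
    return filtered > t3


def wbc_enhanced_mask(image: np.ndarray, nucleus_area: float,
                      params: SegmentationParams) -> np.ndarray:
    """Strategy 2: b/g chromaticity enhancement, adaptive threshold."""
    chroma = rgb_to_rg_chroma(image)
    ien = ratio_enhance(chroma[..., 2], chroma[..., 1])
    if ien.min() == ien.max():
        warnings.warn("constant b/g enhancement (achromatic image); "
                      "mask is degenerate", stacklevel=2)
        return np.zeros(ien.shape, dtype=bool)
    ien = normalize_plane(ien)
    t4 = adaptive_threshold_fraction(ien, nucleus_area, params.N)
    return ien > t4


def build_outside_seeds(image: np.ndarray, nucleus_area: float,
                        params: SegmentationParams) -> np.ndarray:
    """Union of both strategies, denoised and hole-filled.

    Holes arise where the nucleus scores differently from the cytoplasm in
    one channel; they are filled (4-connected background not touching the
    border) because the WBC mask must contain the nucleus seeds for the
    marker-controlled watershed to work.
    """
    union = (wbc_cluster_mask(image, nucleus_area, params)
             | wbc_enhanced_mask(image, nucleus_area, params))
    mask = denoise_small(union, params.S2)
    return ndi.binary_fill_holes(mask)
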