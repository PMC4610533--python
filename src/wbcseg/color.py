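"""Color-space conversions and ratio enhancement.

The whole pipeline rests on three per-pixel color descriptors of the stained
smear:

* **rg chromaticity** ``r = R/(R+G+B)``, ``g = G/(R+G+B)``, ``b = 1-r-g`` —
  invariant to multiplicative illumination changes, which is what makes the
  method robust across labs and lamps.
* **HSI saturation** — the purple nucleus is strongly saturated while the
  pale background is nearly achromatic.
* **CMYK cyan fraction** — cyan ink is high on the blue/purple stained WBC
  and essentially zero on the reddish RBCs and the background.

Two ratio images are derived from these: the nucleus enhancement
``IE = Is / Ig`` (saturation over g-chromaticity, both min-max normalized)
and the WBC enhancement ``Ien = b / g`` in chromaticity space.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "validate_rgb",
    "rgb_to_rg_chroma",
    "rgb_to_hsi_saturation",
    "rgb_to_cmyk_c",
    "normalize_plane",
    "ratio_enhance",
]

MIN_SIDE = 16


def validate_rgb(image: np.ndarray) -> np.ndarray:
    """Check an H×W×3 8-bit RGB array and return it as float64.

    Raises ``ValueError`` for non-3-channel input, out-of-range values or
    images smaller than 16 px on a side.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H×W×3 RGB image, got shape {image.shape}")
    if image.shape[0] < MIN_SIDE or image.shape[1] < MIN_SIDE:
        raise ValueError(
            f"image {image.shape[0]}×{image.shape[1]} smaller than "
            f"{MIN_SIDE}×{MIN_SIDE}")
    arr = image.astype(np.float64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB values must lie in [0, 255]")
    return arr


def rgb_to_rg_chroma(image: np.ndarray) -> np.ndarray:
    """RGB → rg chromaticity, returned as an H×W×3 float array (r, g, b).

    Each channel is the fraction of that primary in the pixel's total
    intensity, so the triple sums to 1 and is unchanged when the pixel is
    scaled by any positive factor (illumination invariance).  Black pixels
    (R+G+B = 0) are achromatic and take (1/3, 1/3, 1/3).
    """
    arr = validate_rgb(image)
    total = arr.sum(axis=2)
    zero = total == 0
    safe = np.where(zero, 1.0, total)
    r = arr[..., 0] / safe
    g = arr[..., 1] / safe
    r[zero] = 1.0 / 3.0
    g[zero] = 1.0 / 3.0
    b = 1.0 - r - g
    return np.dstack([r, g, b])


def rgb_to_hsi_saturation(image: np.ndarray) -> np.ndarray:
    """HSI saturation plane, S = 1 − 3·min(R,G,B)/(R+G+B), in [0, 1].

    Zero-sum (black) pixels get S = 0.
    """
    arr = validate_rgb(image)
    total = arr.sum(axis=2)
    zero = total == 0
    safe = np.where(zero, 1.0, total)
    s = 1.0 - 3.0 * arr.min(axis=2) / safe
    s[zero] = 0.0
    return np.clip(s, 0.0, 1.0)


def rgb_to_cmyk_c(image: np.ndarray, naive: bool = False) -> np.ndarray:
    """Cyan fraction of the CMYK decomposition, in [0, 1].

    Standard key extraction: with R' = R/255 etc. and K = 1 − max(R',G',B'),
    C = (1 − R' − K)/(1 − K); pure black (K = 1) has no chroma and gets
    C = 0.  With ``naive=True`` the plain complement C = 1 − R' is used
    instead (some printed conversions omit key extraction).
    """
    arr = validate_rgb(image) / 255.0
    if naive:
        return 1.0 - arr[..., 0]
    k = 1.0 - arr.max(axis=2)
    denom = 1.0 - k
    black = denom == 0
    safe = np.where(black, 1.0, denom)
    c = (1.0 - arr[..., 0] - k) / safe
    c[black] = 0.0
    return np.clip(c, 0.0, 1.0)


def normalize_plane(plane: np.ndarray) -> np.ndarray:
    """Min-max rescale a scalar plane to the byte range [0, 255].

    A constant plane has no range to stretch and maps to all zeros.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.size == 0:
        raise ValueError("empty plane")
    lo, hi = plane.min(), plane.max()
    if hi == lo:
        return np.zeros_like(plane)
    return (plane - lo) * (255.0 / (hi - lo))


def ratio_enhance(numerator: np.ndarray, denominator: np.ndarray) -> np.ndarray:
    """Pixelwise ratio with a zero fallback on the zero-denominator set."""
    num = np.asarray(numerator, dtype=np.float64)
    den = np.asarray(denominator, dtype=np.float64)
    if num.shape != den.shape:
        raise ValueError(f"shape mismatch {num.shape} vs {den.shape}")
    out = np.zeros_like(num)
    pos = den > 0
    out[pos] = num[pos] / den[pos]
    return out
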