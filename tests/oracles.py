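"""Independent brute-force oracles shared by the test suite."""

import heapq
import math

import numpy as np
from scipy import ndimage as ndi


def mean_shift_oracle(img, hs, hr, max_iters, tol):
    """Pure-Python per-pixel window-mean iteration in the joint domain.

    Sequential raster-order accumulation, mirroring IEEE evaluation order
    so agreement with the production filter can be exact.
    """
    h, w = img.shape
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            py, px, pv = float(i), float(j), float(img[i, j])
            for _ in range(max_iters):
                y0 = max(int(math.ceil(py - hs)), 0)
                y1 = min(int(math.floor(py + hs)), h - 1)
                x0 = max(int(math.ceil(px - hs)), 0)
                x1 = min(int(math.floor(px + hs)), w - 1)
                sy = sx = sv = 0.0
                k = 0
                for yy in range(y0, y1 + 1):
                    for xx in range(x0, x1 + 1):
                        v = float(img[yy, xx])
                        if abs(v - pv) <= hr:
                            sy += yy
                            sx += xx
                            sv += v
                            k += 1
                if k == 0:
                    break
                nv = sv / k
                shift = abs(nv - pv)
                py, px, pv = sy / k, sx / k, nv
                if shift < tol:
                    break
            out[i, j] = pv
    return out


def minimax_flood_levels(outside, markers):
    """Per-marker flood level of every pixel: the minimum over connecting
    paths of the maximum surface height along the path, on the negated
    distance-to-background surface.  A watershed basin assignment is
    consistent iff each pixel's label attains the minimal flood level."""
    h, w = outside.shape
    ids = np.unique(markers[(markers > 0) & outside])
    height = -ndi.distance_transform_edt(outside)
    levels = {}
    for m in ids:
        level = np.full((h, w), np.inf)
        heap = []
        for y, x in zip(*np.nonzero((markers == m) & outside)):
            level[y, x] = height[y, x]
            heapq.heappush(heap, (height[y, x], int(y), int(x)))
        while heap:
            lv, y, x = heapq.heappop(heap)
            if lv > level[y, x]:
                continue
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and outside[ny, nx]:
                    cand = max(lv, height[ny, nx])
                    if cand < level[ny, nx]:
                        level[ny, nx] = cand
                        heapq.heappush(heap, (cand, ny, nx))
        levels[int(m)] = level
    return levels


def watershed_consistent_with_flood_levels(labels, outside, markers,
                                           tol=1e-9):
    """True iff every foreground pixel is assigned to a minimal-flood-level
    marker (ties may go to any tied marker) and unreachable pixels to none."""
    levels = minimax_flood_levels(outside, markers)
    if not levels:
        return not labels[outside].any()
    ids = sorted(levels)
    stack = np.stack([levels[m] for m in ids])
    best = stack.min(axis=0)
    for y, x in zip(*np.nonzero(outside)):
        lab = int(labels[y, x])
        if not np.isfinite(best[y, x]):
            if lab != 0:
                return False
            continue
        if lab == 0 or lab not in ids:
            return False
        if stack[ids.index(lab), y, x] > best[y, x] + tol:
            return False
    return True
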