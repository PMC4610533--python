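"""Synthetic Wright-stain-like blood smear generator with exact ground truth.

Scenes emulate the image properties the segmentation method assumes: a pale
near-achromatic background, anucleate reddish RBC disks, WBCs drawn as a
lilac cytoplasm blob around a dark purple nucleus (optionally multi-lobed,
like a segmented neutrophil), optional clusters of genuinely overlapping
cells, a global multiplicative illumination factor, and additive Gaussian
sensor noise.

Geometry is generated directly at the working resolution at which all
pipeline thresholds are calibrated: isolated WBC radii span 14–30 px
(areas ≈ 600–2800, inside the observed 460–3367 per-type range), cluster
members are drawn from the large-cell end (24–32 px) so that a clump's
area exceeds the adhesion area threshold.  Cell boundaries carry smooth
radial raggedness calibrated so single-cell chain-code roundness falls in
the observed 1.47–3.09 band — real stained cells are far from ideal disks,
and without that raggedness overlapping clumps would never reach the
roundness an adhesive target is stated to have.

Ground truth assigns contested overlap pixels to the cell with the
smallest center distance normalized by cell radius; nucleus pixels always
belong to their own cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as _sk_polygon

__all__ = ["Palette", "SceneSpec", "GroundTruth", "make_smear",
           "apply_illumination"]


@dataclass(frozen=True)
class Palette:
    """Stain colors (RGB, 0-255).

    Chosen so the qualitative stain ordering the method relies on holds
    with margin: the nucleus is the most saturated and poorest in green
    chromaticity; cyan fraction orders nucleus > cytoplasm > RBC ≈
    background; WBC pixels have the highest blue/green chromaticity ratio.
    """

    background: tuple[int, int, int] = (232, 228, 224)
    rbc: tuple[int, int, int] = (217, 136, 128)
    cytoplasm: tuple[int, int, int] = (184, 162, 216)
    nucleus: tuple[int, int, int] = (75, 44, 127)


@dataclass
class SceneSpec:
    """Parameters of one synthetic smear scene."""

    image_size: tuple[int, int] = (360, 480)  # (height, width)
    n_wbc: int = 5
    n_rbc: int = 25
    #: share of WBCs placed in touching/overlapping clusters
    overlap_fraction: float = 0.0
    #: inclusive range of nucleus lobe counts to sample per cell
    lobes_per_nucleus: tuple[int, int] = (1, 2)
    #: global multiplicative illumination factor in (0, 1]
    illumination: float = 1.0
    #: additive Gaussian noise standard deviation, gray levels
    noise_sd: float = 4.0
    seed: int = 0
    palette: Palette = field(default_factory=Palette)
    #: nucleus area as a fraction of the full cell area (1/3 emulates
    #: peripheral blood; 2/3 the thin-cytoplasm bone-marrow blasts)
    nucleus_fraction: float = 1.0 / 3.0
    #: push cluster nuclei together until their masks merge (exercises the
    #: second, marker-free watershed pass)
    merged_nuclei: bool = False
    #: std of the radial boundary perturbation, as a fraction of the radius;
    #: calibrated so single cells score mid-band chain-code roundness while
    #: overlapping clumps exceed the adhesive-target roundness of 3
    roughness: float = 0.15
    wbc_radius_range: tuple[float, float] = (14.0, 30.0)
    cluster_radius_range: tuple[float, float] = (26.0, 30.0)
    rbc_radius_range: tuple[float, float] = (8.0, 12.0)

    def __post_init__(self) -> None:
        if self.n_wbc < 0 or self.n_rbc < 0:
            raise ValueError("counts must be >= 0")
        if not (0 <= self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must be in [0, 1]")
        if not (0 < self.illumination <= 1):
            raise ValueError("illumination must be in (0, 1]")
        if not (0 < self.nucleus_fraction < 1):
            raise ValueError("nucleus_fraction must be in (0, 1)")


@dataclass
class GroundTruth:
    """Pixel-exact reference segmentation of a generated scene."""

    wbc_labels: np.ndarray
    nucleus_labels: np.ndarray
    cell_records: list[dict] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return int(self.wbc_labels.max())


# minimum clearance (px) between the nuclei of distinct non-cluster cells;
# kept above the lobe-connection distance threshold so Phase I never merges
# seeds across separate cells
ISOLATION_NUCLEUS_GAP = 60.0


def _blob_mask(shape: tuple[int, int], center: tuple[float, float],
               radius: float, roughness: float, rng: np.random.Generator,
               n_theta: int = 720, max_harmonic: int = 16) -> np.ndarray:
    """Rasterize a ragged star-convex blob r(θ) = R·(1 + perturbation)."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    pert = np.zeros(n_theta)
    if roughness > 0:
        coeffs = rng.normal(size=max_harmonic - 1)
        phases = rng.uniform(0, 2 * math.pi, size=max_harmonic - 1)
        for m, (c, ph) in enumerate(zip(coeffs, phases), start=2):
            pert += c * np.cos(m * theta + ph)
        sd = pert.std()
        if sd > 0:
            pert *= roughness / sd
        pert = np.clip(pert, -0.4, 0.4)
    r = radius * (1.0 + pert)
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    rr, cc = _sk_polygon(rows, cols, shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _lobe_layout(radius: float, nucleus_area: float, n_lobes: int,
                 rng: np.random.Generator
                 ) -> tuple[list[tuple[float, float]], float]:
    """Lobe center offsets (dy, dx) and lobe radius for one nucleus.

    Lobes sit on a ring around the cell center with small mutual gaps, each
    lobe's area inside the single-lobe band of the multi-core test so that
    the centroid-connected operation can rejoin them.  The lobe count is
    reduced until the layout fits inside the cell.
    """
    for lobes in range(n_lobes, 0, -1):
        lobe_area = nucleus_area / lobes
        if lobes > 1 and not (130.0 <= lobe_area <= 880.0):
            continue
        rl = math.sqrt(lobe_area / math.pi)
        if lobes == 1:
            return [(0.0, 0.0)], rl
        gap = rng.uniform(2.0, 5.0)
        # ring radius giving chord spacing 2*rl + gap between neighbors
        rho = (2.0 * rl + gap) / (2.0 * math.sin(math.pi / lobes))
        # lobes may graze the membrane; the cytoplasm clip truncates them
        if rho + rl > 0.85 * radius:
            continue
        phi0 = rng.uniform(0, 2 * math.pi)
        offs = [(rho * math.sin(phi0 + 2 * math.pi * i / lobes),
                 rho * math.cos(phi0 + 2 * math.pi * i / lobes))
                for i in range(lobes)]
        return offs, rl
    return [(0.0, 0.0)], math.sqrt(nucleus_area / math.pi)


def _chain_layout(size: int, spec: SceneSpec,
                  rng: np.random.Generator) -> list[dict]:
    """A cluster as a local chain of overlapping cells, anchor at (0, 0)."""
    members = [{"cy": 0.0, "cx": 0.0,
                "radius": rng.uniform(*spec.cluster_radius_range)}]
    heading = rng.uniform(0, 2 * math.pi)
    for _ in range(size - 1):
        for _ in range(100):
            r1 = rng.uniform(*spec.cluster_radius_range)
            anchor = members[-1]
            d = rng.uniform(0.84, 0.96) * (anchor["radius"] + r1)
            ang = heading + rng.uniform(-0.9, 0.9)
            y1 = anchor["cy"] + d * math.sin(ang)
            x1 = anchor["cx"] + d * math.cos(ang)
            if all(math.hypot(y1 - c["cy"], x1 - c["cx"])
                   >= 0.75 * (r1 + c["radius"]) for c in members[:-1]):
                members.append({"cy": y1, "cx": x1, "radius": r1})
                heading = ang
                break
        else:  # pragma: no cover - extremely unlikely
            break
    return members


def _place_cells(spec: SceneSpec, rng: np.random.Generator) -> list[dict]:
    """Sample cell centers/radii honoring isolation and cluster geometry.

    Cells of different clusters (and isolated cells) keep their nuclei at
    least ISOLATION_NUCLEUS_GAP apart so the lobe-connection step can never
    bridge distinct cells that are not genuinely overlapping.
    """
    h, w = spec.image_size
    n_cluster_cells = int(round(spec.overlap_fraction * spec.n_wbc))
    if n_cluster_cells == 1:
        n_cluster_cells = 2 if spec.n_wbc >= 2 else 0
    cells: list[dict] = []
    # nucleus extent as a fraction of the cell radius: a multi-lobe ring can
    # reach 0.85r, so the isolation clearance uses 0.9r to be safe
    rn_frac = max(math.sqrt(spec.nucleus_fraction), 0.9)

    def clear_of_others(y, x, r):
        for c in cells:
            d = math.hypot(y - c["cy"], x - c["cx"])
            if d < r * rn_frac + c["radius"] * rn_frac + ISOLATION_NUCLEUS_GAP:
                return False
            if d < r + c["radius"] + 6.0:
                return False
        return True

    cluster_id = 0
    remaining = n_cluster_cells
    while remaining >= 2:
        size = int(min(remaining, rng.integers(2, 4)))
        cluster_id += 1
        placed = False
        for _ in range(600):
            chain = _chain_layout(size, spec, rng)
            ys = [m["cy"] for m in chain]
            xs = [m["cx"] for m in chain]
            rmax = max(m["radius"] for m in chain)
            pad = 1.4 * rmax + 4
            oy_lo, oy_hi = pad - min(ys), h - pad - max(ys)
            ox_lo, ox_hi = pad - min(xs), w - pad - max(xs)
            if oy_lo >= oy_hi or ox_lo >= ox_hi:
                continue
            oy = rng.uniform(oy_lo, oy_hi)
            ox = rng.uniform(ox_lo, ox_hi)
            if all(clear_of_others(m["cy"] + oy, m["cx"] + ox, m["radius"])
                   for m in chain):
                for m in chain:
                    cells.append({"cy": m["cy"] + oy, "cx": m["cx"] + ox,
                                  "radius": m["radius"],
                                  "cluster": cluster_id})
                remaining -= len(chain)
                placed = True
                break
        if not placed:
            raise RuntimeError("infeasible packing: canvas too small for the "
                               "requested clusters")

    n_isolated = spec.n_wbc - len(cells)
    for _ in range(max(n_isolated, 0)):
        ok = False
        for _ in range(600):
            r = rng.uniform(*spec.wbc_radius_range)
            pad = 1.4 * r + 4
            if pad >= h - pad or pad >= w - pad:
                continue
            y = rng.uniform(pad, h - pad)
            x = rng.uniform(pad, w - pad)
            if clear_of_others(y, x, r):
                cells.append({"cy": y, "cx": x, "radius": r, "cluster": 0})
                ok = True
                break
        if not ok:
            raise RuntimeError("infeasible packing: canvas too small for the "
                               "requested cell count")
    return cells


def make_smear(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene.  Deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    shape = (h, w)
    pal = spec.palette

    cells = _place_cells(spec, rng)

    # --- masks ---------------------------------------------------------
    cyto_masks: list[np.ndarray] = []
    nuc_masks: list[np.ndarray] = []
    records: list[dict] = []
    yy, xx = np.mgrid[0:h, 0:w]
    for i, c in enumerate(cells, start=1):
        cy, cx, r = c["cy"], c["cx"], c["radius"]
        cyto = _blob_mask(shape, (cy, cx), r, spec.roughness, rng)
        nucleus_area = spec.nucleus_fraction * math.pi * r * r
        lo, hi = spec.lobes_per_nucleus
        want_lobes = int(rng.integers(lo, hi + 1))
        offs, rl = _lobe_layout(r, nucleus_area, want_lobes, rng)
        # cluster members push their nucleus away from (or, when merged
        # seeds are requested, toward) the nearest cluster partner
        ny, nx = cy, cx
        if c["cluster"]:
            partners = [d for d in cells
                        if d is not c and d["cluster"] == c["cluster"]]
            if partners:
                p = min(partners,
                        key=lambda d: math.hypot(cy - d["cy"], cx - d["cx"]))
                vy, vx = cy - p["cy"], cx - p["cx"]
                nv = math.hypot(vy, vx) or 1.0
                rn = math.sqrt(nucleus_area / math.pi)
                if spec.merged_nuclei:
                    # reach past the waist midpoint so both nuclei overlap
                    # there; the cytoplasm clip below keeps each inside its
                    # own cell
                    shift = max(0.5 * nv - rn + 3.0, 0.0)
                    ny -= shift * vy / nv
                    nx -= shift * vx / nv
                else:
                    shift = min(0.30 * r, max(r - rn - 3.0, 0.0))
                    ny += shift * vy / nv
                    nx += shift * vx / nv
        nuc = np.zeros(shape, dtype=bool)
        lobe_centers = []
        for (dy, dx) in offs:
            lc = (ny + dy, nx + dx)
            lobe_centers.append(lc)
            nuc |= _blob_mask(shape, lc, rl, 0.5 * spec.roughness, rng)
        nuc &= cyto  # nucleus never pokes out of its cell
        cyto_masks.append(cyto)
        nuc_masks.append(nuc)
        records.append({"id": i, "type": "wbc", "center": (cx, cy),
                        "radius": r, "n_lobes": len(offs),
                        "lobe_radius": rl,
                        "lobe_centers": [(x_, y_) for (y_, x_) in lobe_centers],
                        "cluster": c["cluster"]})

    # competitive assignment of contested overlap pixels
    wbc_labels = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf)
    for i, (c, cyto) in enumerate(zip(cells, cyto_masks), start=1):
        score = np.hypot(yy - c["cy"], xx - c["cx"]) / c["radius"]
        take = cyto & (score < best)
        wbc_labels[take] = i
        best[take] = score[take]
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    for i, nuc in enumerate(nuc_masks, start=1):
        own = nuc & ((nucleus_labels == 0) | (wbc_labels == i))
        nucleus_labels[own] = i
    # nuclei sit inside their own cell's territory in the truth
    wbc_labels[nucleus_labels > 0] = nucleus_labels[nucleus_labels > 0]

    # --- rendering -----------------------------------------------------
    img = np.empty((h, w, 3), dtype=np.float64)
    img[...] = np.asarray(pal.background, dtype=np.float64)

    for _ in range(spec.n_rbc):
        r = rng.uniform(*spec.rbc_radius_range)
        for _ in range(200):
            y = rng.uniform(r, h - r)
            x = rng.uniform(r, w - r)
            if all(math.hypot(y - c["cy"], x - c["cx"]) > c["radius"] + r + 2.0
                   for c in cells):
                break
        else:
            continue  # crowded scene: silently drop this RBC
        disk = _blob_mask(shape, (y, x), r, 0.04, rng)
        tint = np.clip(np.asarray(pal.rbc) * rng.normal(1.0, 0.02), 0, 255)
        img[disk] = tint
        # central pallor of the biconcave disk
        pallor = _blob_mask(shape, (y, x), 0.45 * r, 0.05, rng)
        img[pallor] = 0.65 * tint + 0.35 * np.asarray(pal.background)
        records.append({"id": 0, "type": "rbc", "center": (x, y), "radius": r})

    for i, (cyto, nuc) in enumerate(zip(cyto_masks, nuc_masks)):
        ctint = np.clip(np.asarray(pal.cytoplasm) * rng.normal(1.0, 0.02),
                        0, 255)
        ntint = np.clip(np.asarray(pal.nucleus) * rng.normal(1.0, 0.02),
                        0, 255)
        img[cyto & (nucleus_labels == 0)] = ctint
        img[nuc] = ntint

    img *= spec.illumination
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = GroundTruth(wbc_labels=wbc_labels, nucleus_labels=nucleus_labels,
                        cell_records=records)
    return img, truth


def apply_illumination(image: np.ndarray, factor: float) -> np.ndarray:
    """Scale all intensities by ``factor`` ∈ (0, 1] with rounding.

    Because the factor never exceeds 1 no channel can clip, so the rg
    chromaticity of the result matches the original up to the ±0.5 rounding
    quantization per channel.
    """
    if not (0 < factor <= 1):
        raise ValueError("illumination factor must be in (0, 1]")
    image = np.asarray(image)
    return np.clip(np.rint(image.astype(np.float64) * factor),
                   0, 255).astype(np.uint8)
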