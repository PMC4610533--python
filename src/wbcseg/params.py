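"""Segmentation parameters and run configuration.

All pixel thresholds are expressed at the working resolution, i.e. after the
pipeline has downscaled the input by ``resize_factor``.  They were calibrated
from per-cell-type morphology statistics (area, width, roundness, lobe
spacing) measured at that scale, so changing ``resize_factor`` without
rescaling the area/distance thresholds will misbehave.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import yaml

__all__ = ["SegmentationParams", "RunConfig", "N_PERIPHERAL", "N_MARROW"]

#: WBC-area-to-nucleus-area ratio for peripheral blood smears.
N_PERIPHERAL = 3.0
#: WBC-area-to-nucleus-area ratio for bone-marrow smears (leukemic blasts
#: carry proportionally larger nuclei, so the cytoplasm margin is thinner).
N_MARROW = 1.5


@dataclass
class SegmentationParams:
    """Every tunable threshold of the four-phase WBC segmentation.

    Areas and distances are in pixels at working scale; intensity bandwidths
    are in 8-bit gray levels.
    """

    #: minimum nucleus component area kept by morphological denoising
    S1: int = 100
    #: minimum WBC component area kept by morphological denoising
    S2: int = 350
    #: centroid fluctuation padding of the lobe-connecting rectangle
    T2: int = 5
    #: maximum boundary-to-boundary distance for two nucleus lobes to be
    #: considered parts of one segmented (multi-lobed) nucleus
    l11: float = 55.0
    #: single-lobe area bounds (strict) for the multi-core test
    s11: int = 100
    s12: int = 950
    #: adhesive-region area threshold (strict, >)
    S3: int = 3500
    #: adhesive-region roundness threshold (strict, >)
    R: float = 3.00
    #: distance-transform height defining local extremum regions in the
    #: second (adaptive) watershed pass
    Rs: float = 7.0
    #: mean-shift spatial (Chebyshev) bandwidth
    hs: int = 3
    #: mean-shift intensity bandwidth
    hr: float = 3.0
    #: mean-shift iteration cap
    ms_max_iters: int = 4
    #: mean-shift intensity-shift convergence tolerance
    ms_convergence_tol: float = 0.5
    #: WBC-to-nucleus area ratio (3 peripheral, 1.5 marrow)
    N: float = N_PERIPHERAL
    #: downscale applied to the raw micrograph before any processing
    resize_factor: float = 0.2
    #: IoU at which a predicted cell counts as a correct segmentation
    iou_match: float = 0.5
    #: use the naive C = 1 - R/255 cyan conversion instead of key extraction
    cmyk_naive: bool = False
    #: disk radius of the erosion/dilation structuring element
    se_radius: int = 3
    #: comparator for the roundness half of the adhesion test; the
    #: calibration section uses ">" (adhesive clumps are *less* round in the
    #: compactness sense, i.e. larger values)
    adhesion_roundness_cmp: Literal["gt", "lt"] = "gt"
    #: topographic surface for the marked watershed
    watershed_surface: Literal["dist_to_bg", "dist_to_seed"] = "dist_to_bg"

    def __post_init__(self) -> None:
        if not (self.s11 < self.s12):
            raise ValueError("s11 must be < s12")
        if self.N <= 1:
            raise ValueError("N must exceed 1 (WBC strictly larger than nucleus)")
        if not (0 < self.resize_factor <= 1):
            raise ValueError("resize_factor must be in (0, 1]")
        for name in ("S1", "S2", "T2", "l11", "s11", "s12", "S3", "Rs", "hs", "hr",
                     "se_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2) if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def from_file(cls, path: str | Path) -> "SegmentationParams":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)

    def replace(self, **kw) -> "SegmentationParams":
        return dataclasses.replace(self, **kw)

    @classmethod
    def for_smear(cls, smear_type: str, **kw) -> "SegmentationParams":
        """Defaults with the area ratio N selected by smear type."""
        if smear_type == "peripheral":
            n = N_PERIPHERAL
        elif smear_type == "marrow":
            n = N_MARROW
        else:
            raise ValueError("smear_type must be 'peripheral' or 'marrow'")
        return cls(N=n, **kw)


@dataclass
class RunConfig:
    """Pipeline-level options wrapping :class:`SegmentationParams`."""

    smear_type: Literal["peripheral", "marrow"] = "peripheral"
    params: SegmentationParams | None = None
    debug_dir: Path | None = None
    overlay: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.smear_type not in ("peripheral", "marrow"):
            raise ValueError("smear_type must be 'peripheral' or 'marrow'")
        if self.params is None:
            self.params = SegmentationParams.for_smear(self.smear_type)
        if self.debug_dir is not None:
            self.debug_dir = Path(self.debug_dir)
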