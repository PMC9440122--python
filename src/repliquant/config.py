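"""Analysis configuration.

All tunable thresholds of the quantification pipeline live in one dataclass
so that every output table can record the exact parameters used.  Defaults
are the values of the original semi-automated analysis: intensity floors of
3000 (nuclear) and 7000 (heterochromatin) on the 16-bit scale, circular ROIs
of radius 4 px (accumulation) and 5 px (modification levels), three ROIs per
compartment, and the expression-grouping bins for GFP and mCherry in
arbitrary units (AU).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Tuple

import yaml

#: (label, lower, upper) half-open [lower, upper) bins per fluorophore, in AU.
DEFAULT_EXPRESSION_BINS: Dict[str, List[Tuple[str, float, float]]] = {
    "gfp": [
        ("background", 0.0, 50.0),
        ("low", 50.0, 100.0),
        ("mid", 100.0, 500.0),
        ("high", 500.0, 1000.0),
    ],
    "mcherry": [
        ("background", 0.0, 100.0),
        ("low", 100.0, 500.0),
        ("mid", 500.0, 1000.0),
        ("high", 1000.0, 5000.0),
    ],
}


class ConfigError(ValueError):
    """Invalid analysis configuration."""


@dataclass
class AnalysisConfig:
    """Parameters of the image-quantification pipeline.

    Attributes
    ----------
    nuclear_floor : float
        Minimum DNA-counterstain intensity for the nuclear mask (16-bit AU).
    het_floor : float
        Minimum intensity for the heterochromatin (chromocenter) mask.
    roi_radius_accumulation : int
        Radius (px) of the circular ROIs used for the accumulation ratio.
    roi_radius_modlevel : int
        Radius (px) of the ROIs placed on DAPI-dense regions.
    n_rois : int
        Number of ROIs per compartment (foci and nucleoplasm).
    gfp_background, mcherry_background : float
        Mean fluorophore intensity below which a cell counts as untransfected.
    expression_bins : dict
        Per-fluorophore ordered, non-overlapping [lo, hi) bins.
    min_nucleus_area : int
        Connected components smaller than this (px) are discarded.
    n_compaction_classes : int
        Number of chromatin-compaction intensity classes.
    rng_seed : int
        Global seed; every stochastic step derives its stream from it.
    """

    nuclear_floor: float = 3000.0
    het_floor: float = 7000.0
    roi_radius_accumulation: int = 4
    roi_radius_modlevel: int = 5
    n_rois: int = 3
    gfp_background: float = 50.0
    mcherry_background: float = 100.0
    expression_bins: Dict[str, List[Tuple[str, float, float]]] = field(
        default_factory=lambda: {
            k: list(v) for k, v in DEFAULT_EXPRESSION_BINS.items()
        }
    )
    min_nucleus_area: int = 500
    n_compaction_classes: int = 7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.nuclear_floor <= 0 or self.het_floor <= 0:
            raise ConfigError("intensity floors must be positive")
        if self.het_floor < self.nuclear_floor:
            raise ConfigError("het_floor must be >= nuclear_floor")
        if self.roi_radius_accumulation <= 0 or self.roi_radius_modlevel <= 0:
            raise ConfigError("ROI radii must be positive")
        if self.n_rois < 1:
            raise ConfigError("n_rois must be >= 1")
        if self.n_compaction_classes < 2:
            raise ConfigError("need at least 2 compaction classes")
        for fp, bins in self.expression_bins.items():
            prev_hi = None
            for label, lo, hi in bins:
                if hi <= lo:
                    raise ConfigError(f"{fp} bin {label!r}: hi <= lo")
                if prev_hi is not None and lo != prev_hi:
                    raise ConfigError(
                        f"{fp} bins must be contiguous and ordered"
                    )
                prev_hi = hi

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["expression_bins"] = {
            k: [list(b) for b in v] for k, v in self.expression_bins.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "expression_bins" in data:
            data["expression_bins"] = {
                k: [tuple(b) for b in v]
                for k, v in data["expression_bins"].items()
            }
        return cls(**data)
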