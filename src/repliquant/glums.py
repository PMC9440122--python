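"""Gel densitometry and GluMS-PCR inference of locus-level 5mC / 5hmC.

GluMS-PCR combines T4-BGT glucosylation with methylation-sensitive
restriction and PCR across a CCGG site.  The cleavage rules are: HpaII
cleaves only unmodified sites; MspI cleaves unmodified C, 5mC and 5hmC but
not glucosylated 5hmC (5ghmC).  A surviving (uncleaved) template yields a
PCR band, so with band densities normalized to the undigested control D0:

* +BGT MspI survival minus the −BGT MspI control gives the 5hmC fraction;
* HpaII survival gives the total modified (5mC + 5hmC) fraction;
* their difference gives the 5mC fraction.

All levels are clipped to [0, 1] with explicit clip flags.  The model
assumes a single CCGG site per amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np


class UninterpretablePanelError(ValueError):
    """Undigested control density is zero."""


@dataclass
class GelLane:
    lane_id: str
    rectangle: Tuple[int, int, int, int]  # (row0, row1, col0, col1)
    density: float

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be >= 0")


def lane_density(
    gel: np.ndarray,
    rectangle: Tuple[int, int, int, int],
    lane_id: str = "lane",
) -> GelLane:
    """Background-subtracted integrated density of one lane rectangle.

    The intensity profile is the row-wise sum across the lane width; a
    linear baseline between the profile endpoints is subtracted and the
    remaining area integrated (negative totals floored at 0).
    """
    gel = np.asarray(gel, dtype=float)
    r0, r1, c0, c1 = rectangle
    if not (0 <= r0 < r1 <= gel.shape[0] and 0 <= c0 < c1 <= gel.shape[1]):
        raise ValueError(f"rectangle {rectangle} outside image {gel.shape}")
    profile = gel[r0:r1, c0:c1].sum(axis=1)
    baseline = np.linspace(profile[0], profile[-1], profile.size)
    density = max(float((profile - baseline).sum()), 0.0)
    return GelLane(lane_id=lane_id, rectangle=rectangle, density=density)


@dataclass
class DigestPanel:
    """Band densities of the (±BGT) × (undigested / MspI / HpaII) design."""

    undigested: float  # D0
    mspi_minus_bgt: float  # Dm: MspI on non-glucosylated DNA
    mspi_plus_bgt: float  # Dg: MspI on glucosylated DNA
    hpaii: float  # Dh
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        for name in ("undigested", "mspi_minus_bgt", "mspi_plus_bgt",
                     "hpaii"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} density must be >= 0")


@dataclass
class GlumsResult:
    sample_id: str
    hmc_level: float
    mc_level: float
    modified_level: float  # 5mC + 5hmC (HpaII survival)
    clipped: bool


def glums_infer(panel: DigestPanel) -> GlumsResult:
    """Locus-level 5hmC and 5mC fractions from a digest panel.

    ``hmc = max(Dg − Dm, 0)/D0`` (glucosyl-protected MspI survival minus
    the non-glucosylated control); ``modified = Dh/D0`` (HpaII survival =
    5mC + 5hmC); ``mc = max(modified − hmc, 0)``; everything clipped to
    [0, 1] with a flag recording whether any clip fired.
    """
    if panel.undigested <= 0:
        raise UninterpretablePanelError(
            "undigested control density must be positive"
        )
    d0 = panel.undigested
    raw_hmc = (panel.mspi_plus_bgt - panel.mspi_minus_bgt) / d0
    raw_mod = panel.hpaii / d0
    hmc = min(max(raw_hmc, 0.0), 1.0)
    mod = min(max(raw_mod, 0.0), 1.0)
    raw_mc = mod - hmc
    mc = min(max(raw_mc, 0.0), 1.0)
    clipped = (raw_hmc != hmc) or (raw_mod != mod) or (raw_mc != mc)
    return GlumsResult(
        sample_id=panel.sample_id,
        hmc_level=hmc,
        mc_level=mc,
        modified_level=mod,
        clipped=clipped,
    )
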