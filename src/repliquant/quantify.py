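"""Per-cell quantification: accumulation at replicating heterochromatin,
in situ modification levels with normalization and expression grouping,
modification ratios, decondensation metrics, and F3H colocalization scoring.

The central readout is the *relative accumulation*: the mean intensity of
the protein of interest in three circular ROIs placed on PCNA-marked
replication foci, divided by the mean in three same-sized nucleoplasmic
ROIs.  Auto mode places the foci ROIs on the brightest PCNA maxima inside
heterochromatin and samples the nucleoplasm ROIs uniformly (seeded);
manual mode reproduces hand-picked ROI centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max

from .config import AnalysisConfig
from .io import NucleusImage
from .segmentation import CircularROI, MaskSet, disk_mask


class InsufficientRegionError(RuntimeError):
    """Fewer candidate foci or nucleoplasm pixels than ROIs requested."""


class UndefinedRatioError(ZeroDivisionError):
    """Ratio denominator is zero."""


class NormalizationError(ValueError):
    """Non-positive normalization denominator."""


@dataclass
class AccumulationResult:
    cell_id: str
    foci_rois: List[CircularROI]
    nucleoplasm_rois: List[CircularROI]
    mean_in_foci: float
    mean_in_nucleoplasm: float
    relative_accumulation: float


def _roi_means(protein: np.ndarray, rois: Sequence[CircularROI]) -> np.ndarray:
    return np.array([protein[r.mask].mean() for r in rois])


def relative_accumulation(
    img: NucleusImage,
    masks: MaskSet,
    cfg: Optional[AnalysisConfig] = None,
    mode: str = "auto",
    manual_foci: Optional[Sequence[Tuple[float, float]]] = None,
    manual_nucleoplasm: Optional[Sequence[Tuple[float, float]]] = None,
    seed: Optional[int] = None,
    cell_id: str = "cell",
) -> AccumulationResult:
    """Protein enrichment at PCNA-marked replicating heterochromatin.

    Auto mode selects the ``cfg.n_rois`` brightest local maxima of the
    (Gaussian-smoothed) PCNA channel within the heterochromatin mask, with
    a minimum separation of twice the ROI radius, and samples ``cfg.n_rois``
    nucleoplasm centers uniformly from the nucleoplasm eroded by the ROI
    radius.  Returns the ratio of the averaged ROI means (foci over
    nucleoplasm).
    """
    cfg = cfg or AnalysisConfig()
    protein = np.asarray(img.channel("protein"), dtype=float)
    r = cfg.roi_radius_accumulation
    shape = protein.shape

    if mode == "manual":
        if manual_foci is None or manual_nucleoplasm is None:
            raise ValueError("manual mode requires both ROI center lists")
        foci_centers = list(manual_foci)
        nuc_centers = list(manual_nucleoplasm)
    elif mode == "auto":
        pcna = np.asarray(img.channel("pcna"), dtype=float)
        smooth = ndi.gaussian_filter(pcna, sigma=r / 2.0)
        candidate = np.where(masks.heterochromatin, smooth, 0.0)
        peaks = peak_local_max(
            candidate,
            min_distance=2 * r,
            num_peaks=cfg.n_rois,
            exclude_border=False,
        )
        if len(peaks) < cfg.n_rois:
            raise InsufficientRegionError(
                f"found {len(peaks)} PCNA foci, need {cfg.n_rois}"
            )
        foci_centers = [tuple(map(float, p)) for p in peaks]

        eroded = ndi.binary_erosion(
            masks.nucleoplasm, structure=disk_mask((2 * r + 1,) * 2, (r, r), r)
        )
        coords = np.argwhere(eroded)
        if len(coords) < cfg.n_rois:
            raise InsufficientRegionError(
                "nucleoplasm too small for requested ROIs"
            )
        rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
        pick = rng.choice(len(coords), size=cfg.n_rois, replace=False)
        nuc_centers = [tuple(map(float, coords[i])) for i in pick]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    foci_rois = [
        CircularROI(c, r, disk_mask(shape, c, r) & masks.nuclear)
        for c in foci_centers
    ]
    nuc_rois = [
        CircularROI(c, r, disk_mask(shape, c, r) & masks.nuclear)
        for c in nuc_centers
    ]
    for roi in foci_rois + nuc_rois:
        if roi.area == 0:
            raise InsufficientRegionError("ROI falls outside the nucleus")

    mean_foci = float(_roi_means(protein, foci_rois).mean())
    mean_nuc = float(_roi_means(protein, nuc_rois).mean())
    if mean_nuc == 0:
        raise UndefinedRatioError("nucleoplasm mean intensity is zero")
    return AccumulationResult(
        cell_id=cell_id,
        foci_rois=foci_rois,
        nucleoplasm_rois=nuc_rois,
        mean_in_foci=mean_foci,
        mean_in_nucleoplasm=mean_nuc,
        relative_accumulation=mean_foci / mean_nuc,
    )


def normalize_mod_level(
    sum_mod: float, sum_dapi: float, background_mean_mod: float
) -> float:
    """Background- and DNA-normalized modification level.

    The sum nuclear modification signal is divided by the mean signal of
    below-background cells, then by the sum nuclear DNA counterstain
    intensity (compensating cell-cycle-dependent DNA content).
    """
    if sum_dapi <= 0 or background_mean_mod <= 0:
        raise NormalizationError(
            "sum_dapi and background_mean_mod must be positive"
        )
    if sum_mod < 0:
        raise NormalizationError("sum_mod must be >= 0")
    return (sum_mod / background_mean_mod) / sum_dapi


class ExpressionGroup(NamedTuple):
    group: str
    out_of_range: bool


def group_by_expression(
    mean_fp: float, fluorophore: str, cfg: Optional[AnalysisConfig] = None
) -> ExpressionGroup:
    """Expression-group label from the mean fluorophore intensity (AU).

    Bins are half-open ``[lo, hi)``; values above the top bin are labeled
    ``high`` with ``out_of_range=True``.
    """
    cfg = cfg or AnalysisConfig()
    if mean_fp < 0:
        raise ValueError("mean_fp must be >= 0")
    try:
        bins = cfg.expression_bins[fluorophore]
    except KeyError:
        raise ValueError(f"unknown fluorophore {fluorophore!r}") from None
    for label, lo, hi in bins:
        if lo <= mean_fp < hi:
            return ExpressionGroup(label, False)
    return ExpressionGroup(bins[-1][0], True)


def mod_ratio(norm_mod: float, norm_5mc: float) -> float:
    """Modification level relative to the matched normalized 5mC level."""
    if norm_5mc <= 0:
        raise UndefinedRatioError("normalized 5mC level must be positive")
    return norm_mod / norm_5mc


@dataclass
class DecondensationMetrics:
    cell_id: str
    relative_het_area: float
    dapi_sd: float


def decondensation_metrics(
    img: NucleusImage, masks: MaskSet, cell_id: str = "cell"
) -> DecondensationMetrics:
    """Chromatin-decondensation readouts.

    The DAPI-dense heterochromatin area divided by the total nuclear area,
    and the standard deviation of DNA-channel intensities within the
    nucleus (both shrink as heterochromatin decondenses).
    """
    if not masks.nuclear.any():
        raise ValueError("empty nuclear mask")
    dna = np.asarray(img.channel("dna"), dtype=float)
    if dna.ndim == 3:
        dna = dna.max(axis=0)
    return DecondensationMetrics(
        cell_id=cell_id,
        relative_het_area=float(masks.heterochromatin.sum())
        / float(masks.nuclear.sum()),
        dapi_sd=float(dna[masks.nuclear].std()),
    )


F3H_MIN_CELLS = 50


def f3h_score(
    cells: Sequence[Tuple[str, bool]]
) -> pd.DataFrame:
    """Percentage of cells with bait-prey colocalization per S-phase stage.

    ``cells`` holds (stage, colocalized) pairs.  A stage with fewer than 50
    scored cells is kept but flagged with a low-n warning.
    """
    if not cells:
        raise ValueError("no cells to score")
    frame = pd.DataFrame(cells, columns=["stage", "colocalized"])
    bad = set(frame["stage"]) - {"earlyS", "lateS", "nonS", "unknown"}
    if bad:
        raise ValueError(f"unknown stage labels: {sorted(bad)}")
    out = (
        frame.groupby("stage", sort=True)["colocalized"]
        .agg(n="size", n_colocalized="sum")
        .reset_index()
    )
    out["percent"] = 100.0 * out["n_colocalized"] / out["n"]
    out["low_n"] = out["n"] < F3H_MIN_CELLS
    for _, row in out[out["low_n"]].iterrows():
        warnings.warn(
            f"stage {row['stage']}: only {row['n']} cells "
            f"(< {F3H_MIN_CELLS})",
            stacklevel=2,
        )
    return out
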