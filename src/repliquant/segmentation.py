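"""Nuclear, heterochromatin and nucleoplasm masks from the DNA counterstain.

The nuclear mask keeps pixels above the larger of the triangle threshold
(256-bin histogram) and a fixed floor of 3000 (16-bit AU), with holes
filled and small components removed.  Within each nucleus, the
heterochromatin (chromocenter) mask keeps pixels above the larger of the
triangle threshold of within-nucleus intensities and a floor of 7000; the
nucleoplasm is the remainder of the nucleus, so the three masks always form
an exact partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_triangle
from skimage.measure import label as sk_label
from skimage.morphology import remove_small_objects

from .config import AnalysisConfig
from .io import NucleusImage, max_project


class DegenerateHistogramError(ValueError):
    """Constant image: no threshold exists."""


@dataclass
class MaskSet:
    """Boolean nuclear / heterochromatin / nucleoplasm masks.

    Invariants: heterochromatin is a subset of nuclear; nucleoplasm is the
    set difference nuclear minus heterochromatin; labels index connected
    nuclear components (0 = background).
    """

    nuclear: np.ndarray
    heterochromatin: np.ndarray
    nucleoplasm: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.heterochromatin & ~self.nuclear):
            raise ValueError("heterochromatin must be a subset of nuclear")
        if not np.array_equal(
            self.nucleoplasm, self.nuclear & ~self.heterochromatin
        ):
            raise ValueError("nucleoplasm must equal nuclear \\ heterochromatin")

    @property
    def n_nuclei(self) -> int:
        return int(self.labels.max())


def _dna_plane(img: NucleusImage) -> np.ndarray:
    dna = img.channel("dna")
    if dna.ndim == 3:
        dna = max_project(img).channel("dna")
    return dna


def triangle_threshold(plane: np.ndarray, nbins: int = 256) -> float:
    """Triangle-method threshold on an intensity histogram.

    The threshold is the histogram bin with maximal perpendicular distance
    to the chord joining the histogram peak and the farthest empty bin.
    """
    plane = np.asarray(plane)
    if plane.min() == plane.max():
        raise DegenerateHistogramError(
            "constant image: triangle threshold undefined"
        )
    return float(threshold_triangle(plane, nbins=nbins))


def nuclear_mask(
    img: NucleusImage, cfg: Optional[AnalysisConfig] = None
) -> MaskSet:
    """Segment nuclei on the DNA channel.

    Effective threshold = max(triangle threshold, ``cfg.nuclear_floor``);
    pixels strictly above it are kept, holes filled, components below
    ``cfg.min_nucleus_area`` px removed.  Returns a MaskSet with an empty
    heterochromatin mask (see :func:`heterochromatin_mask`).
    """
    cfg = cfg or AnalysisConfig()
    dna = _dna_plane(img)
    try:
        thr = max(triangle_threshold(dna), cfg.nuclear_floor)
    except DegenerateHistogramError:
        thr = cfg.nuclear_floor
    mask = dna > thr
    mask = ndi.binary_fill_holes(mask)
    mask = remove_small_objects(mask, max_size=cfg.min_nucleus_area - 1)
    if not mask.any():
        warnings.warn("no pixels above nuclear threshold: empty mask",
                      stacklevel=2)
    labels = sk_label(mask)
    empty = np.zeros_like(mask)
    return MaskSet(
        nuclear=mask, heterochromatin=empty,
        nucleoplasm=mask & ~empty, labels=labels,
    )


def heterochromatin_mask(
    img: NucleusImage, masks: MaskSet, cfg: Optional[AnalysisConfig] = None
) -> MaskSet:
    """Add the heterochromatin / nucleoplasm partition to a nuclear mask.

    The triangle threshold is computed on within-nucleus intensities only,
    then combined with ``cfg.het_floor`` by max; the mask may be empty.
    """
    cfg = cfg or AnalysisConfig()
    dna = _dna_plane(img)
    nuclear = masks.nuclear
    inside = dna[nuclear]
    thr = cfg.het_floor
    if inside.size and inside.min() != inside.max():
        thr = max(triangle_threshold(inside), cfg.het_floor)
    het = nuclear & (dna > thr)
    return MaskSet(
        nuclear=nuclear,
        heterochromatin=het,
        nucleoplasm=nuclear & ~het,
        labels=masks.labels,
    )


def segment(
    img: NucleusImage, cfg: Optional[AnalysisConfig] = None
) -> MaskSet:
    """Full segmentation: nuclear mask then heterochromatin partition."""
    cfg = cfg or AnalysisConfig()
    return heterochromatin_mask(img, nuclear_mask(img, cfg), cfg)


@dataclass
class CircularROI:
    """A circular region of interest clipped to the nuclear mask."""

    center: Tuple[float, float]  # (y, x)
    radius: float
    mask: np.ndarray

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def disk_mask(
    shape: Tuple[int, int], center: Tuple[float, float], radius: float
) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def dapi_dense_rois(
    img: NucleusImage, masks: MaskSet, cfg: Optional[AnalysisConfig] = None
) -> List[CircularROI]:
    """One circular ROI per DAPI-dense (heterochromatin) component.

    Circles of radius ``cfg.roi_radius_modlevel`` are centered on component
    centroids and clipped to the nuclear mask; an empty heterochromatin
    mask yields an empty list.
    """
    cfg = cfg or AnalysisConfig()
    het = masks.heterochromatin
    if not het.any():
        return []
    comp_labels, n = ndi.label(het)
    centroids = ndi.center_of_mass(het, comp_labels, range(1, n + 1))
    rois = []
    for c in centroids:
        m = disk_mask(het.shape, c, cfg.roi_radius_modlevel) & masks.nuclear
        rois.append(
            CircularROI(center=tuple(c), radius=cfg.roi_radius_modlevel,
                        mask=m)
        )
    return rois
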