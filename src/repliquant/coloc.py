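"""Pearson colocalization within the nuclear mask and line-profile
extraction.

The Pearson coefficient is computed over all in-mask pixels (voxels for a
stack) of two channels; no automatic thresholding is applied, matching a
plain whole-nucleus Coloc2-style analysis.  Line profiles sample each
channel along a segment at unit spacing with bilinear interpolation,
optionally averaged over a perpendicular width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .io import NucleusImage


class UndefinedCorrelationError(ValueError):
    """Zero variance in a channel: correlation undefined."""


@dataclass
class ColocResult:
    cell_id: str
    pearson_r: float
    n_pixels: int
    channel_pair: Tuple[str, str]

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if self.n_pixels < 2:
            raise ValueError("need at least 2 pixels")


def pearson(
    plane_a: np.ndarray,
    plane_b: np.ndarray,
    mask: np.ndarray,
    channel_pair: Tuple[str, str] = ("a", "b"),
    cell_id: str = "cell",
    intensity_floor: Optional[float] = None,
) -> ColocResult:
    """Pearson correlation of two channels over mask pixels.

    Works on 2-D planes or 3-D stacks (all in-mask voxels pooled).  An
    optional intensity floor restricts the mask to pixels above it in
    either channel.
    """
    a = np.asarray(plane_a, dtype=float)
    b = np.asarray(plane_b, dtype=float)
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("planes and mask must share one shape")
    m = mask.astype(bool)
    if intensity_floor is not None:
        m = m & ((a > intensity_floor) | (b > intensity_floor))
    av, bv = a[m], b[m]
    if av.size < 2:
        raise UndefinedCorrelationError("fewer than 2 masked pixels")
    if av.std() == 0 or bv.std() == 0:
        raise UndefinedCorrelationError(
            "zero variance in a channel within the mask"
        )
    r = float(np.corrcoef(av, bv)[0, 1])
    return ColocResult(
        cell_id=cell_id,
        pearson_r=min(max(r, -1.0), 1.0),
        n_pixels=int(av.size),
        channel_pair=channel_pair,
    )


@dataclass
class LineProfile:
    """Intensity profile along a segment, one array per channel."""

    endpoints: Tuple[Tuple[float, float], Tuple[float, float]]
    positions: np.ndarray  # px (or µm if pixel_size known)
    profiles: Dict[str, np.ndarray]
    width: int

    def __post_init__(self) -> None:
        lengths = {v.size for v in self.profiles.values()}
        if lengths != {self.positions.size}:
            raise ValueError("profile arrays must match positions length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


def line_profile(
    img: NucleusImage,
    p0: Tuple[float, float],
    p1: Tuple[float, float],
    width: int = 1,
) -> LineProfile:
    """Sample all channels along the segment p0 -> p1 ((y, x) coordinates).

    Positions are spaced 1 px apart (endpoint included); values are
    bilinearly interpolated and averaged over ``width`` (odd) perpendicular
    offsets.  Stacks are sampled on their maximum projection.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be odd and >= 1")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise ValueError("zero-length segment")
    direction = (p1 - p0) / length
    normal = np.array([-direction[1], direction[0]])
    distances = np.arange(0.0, np.floor(length) + 1.0)
    offsets = np.arange(width) - (width - 1) / 2.0

    profiles: Dict[str, np.ndarray] = {}
    for role, arr in img.channels.items():
        plane = np.asarray(arr, dtype=float)
        if plane.ndim == 3:
            plane = plane.max(axis=0)
        samples = np.zeros_like(distances)
        for off in offsets:
            pts = p0[None, :] + distances[:, None] * direction + off * normal
            samples += ndi.map_coordinates(
                plane, pts.T, order=1, mode="nearest"
            )
        profiles[role] = samples / width

    positions = distances
    if img.pixel_size is not None:
        positions = distances * img.pixel_size
    return LineProfile(
        endpoints=(tuple(p0), tuple(p1)),
        positions=positions,
        profiles=profiles,
        width=width,
    )
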