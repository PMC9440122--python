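"""Image and table IO: the ``NucleusImage`` container, TIFF reading,
maximum-intensity Z-projection, and per-cell CSV tables.

Conventions
-----------
Arrays are indexed ``(z, y, x)`` (stacks) or ``(y, x)`` (projections /
single planes), 0-based.  A ``NucleusImage`` holds one plane or stack per
channel *role* — ``dna`` (counterstain), ``pcna`` (replication foci),
``protein`` (protein of interest), ``mod`` (modification immunostain),
``aux``.  Intensities are kept on their native integer scale; the analysis
thresholds assume the 16-bit range ``[0, 65535]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import tifffile

CHANNEL_ROLES = ("dna", "pcna", "protein", "mod", "aux")

MAX_UINT16 = 65535


class FormatError(ValueError):
    """Unreadable or structurally invalid input file."""


class SchemaError(ValueError):
    """Heterogeneous record schemas."""


@dataclass
class NucleusImage:
    """Registered multi-channel intensity image (projection or Z-stack).

    ``channels`` maps a role name to an array of shape ``(y, x)`` or
    ``(z, y, x)``; all planes must share one shape.
    """

    channels: Dict[str, np.ndarray]
    pixel_size: Optional[float] = None  # µm / px
    is_projection: bool = True
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel is required")
        shapes = {arr.shape for arr in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel planes differ in shape: {shapes}")
        for role, arr in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
            if arr.min() < 0 or arr.max() > MAX_UINT16:
                raise ValueError(
                    f"channel {role!r} intensities outside [0, {MAX_UINT16}]"
                )

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    @property
    def is_stack(self) -> bool:
        return next(iter(self.channels.values())).ndim == 3

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(f"channel role {role!r} not present") from None


def read_image(
    path: str | Path, channel_map: Mapping[int, str]
) -> NucleusImage:
    """Read a grayscale multi-plane TIFF into a :class:`NucleusImage`.

    ``channel_map`` assigns a role to each channel plane index.  2-D files
    are a single channel; 3-D arrays are interpreted as ``(c, y, x)`` when
    the leading axis length equals ``len(channel_map)`` and as a
    single-channel Z-stack otherwise; 4-D arrays are taken as
    ``(z, c, y, x)`` (ImageJ hyperstack order).  8-bit inputs are kept on
    their native scale (``bit_depth`` records it).
    """
    roles = list(channel_map.values())
    if len(set(roles)) != len(roles):
        raise FormatError(f"duplicated channel roles in {channel_map}")
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - normalize reader failures
        raise FormatError(f"cannot read {path!r} as TIFF: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim >= 3 and arr.shape[-1] in (3, 4) and arr.dtype == np.uint8:
        raise FormatError("color (RGB/RGBA) images are not supported")
    if arr.dtype not in (np.uint8, np.uint16, np.int16, np.int32):
        raise FormatError(f"unsupported pixel dtype {arr.dtype}")

    n_chan = len(channel_map)
    if arr.ndim == 2:
        planes = arr[None]
        is_stack = False
    elif arr.ndim == 3:
        if arr.shape[0] == n_chan:
            planes = arr
            is_stack = False
        elif n_chan == 1:
            planes = arr[None]  # single-channel Z-stack
            is_stack = True
        else:
            raise FormatError(
                f"3-D array of shape {arr.shape} does not match "
                f"{n_chan} mapped channels"
            )
    elif arr.ndim == 4:  # (z, c, y, x)
        if arr.shape[1] != n_chan:
            raise FormatError(
                f"4-D array of shape {arr.shape} does not match "
                f"{n_chan} mapped channels"
            )
        planes = np.moveaxis(arr, 1, 0)  # -> (c, z, y, x)
        is_stack = True
    else:
        raise FormatError(f"unsupported array rank {arr.ndim}")

    if max(channel_map) >= planes.shape[0] or min(channel_map) < 0:
        raise FormatError("channel_map index out of range")

    channels = {role: planes[idx] for idx, role in channel_map.items()}
    bit_depth = 8 if arr.dtype == np.uint8 else 16
    return NucleusImage(
        channels=channels, is_projection=not is_stack, bit_depth=bit_depth
    )


def write_image(img: NucleusImage, path: str | Path) -> None:
    """Write channels as a multi-plane 16-bit TIFF (channel axis first)."""
    stack = np.stack([img.channels[r] for r in sorted(img.channels)])
    if img.is_stack:
        stack = np.moveaxis(stack, 0, 1)  # (z, c, y, x)
    tifffile.imwrite(str(path), stack.astype(np.uint16))


def max_project(img: NucleusImage) -> NucleusImage:
    """Per-channel pixelwise maximum over the Z axis.

    A projection input is returned unchanged with a warning (no-op).
    """
    if not img.is_stack:
        warnings.warn(
            "image is already a projection; max_project is a no-op",
            stacklevel=2,
        )
        return img
    channels = {role: arr.max(axis=0) for role, arr in img.channels.items()}
    return NucleusImage(
        channels=channels,
        pixel_size=img.pixel_size,
        is_projection=True,
        bit_depth=img.bit_depth,
    )


@dataclass
class CellRecord:
    """Per-cell measurement row for the high-content tables.

    Holds raw per-channel mean and sum nuclear intensities plus any derived
    normalized values, an expression-group label, and an S-phase stage label.
    """

    cell_id: str
    mean_intensity: Dict[str, float] = field(default_factory=dict)
    sum_intensity: Dict[str, float] = field(default_factory=dict)
    derived: Dict[str, float] = field(default_factory=dict)
    expression_group: str = "unknown"
    stage: str = "unknown"

    STAGES = ("earlyS", "lateS", "nonS", "unknown")

    def __post_init__(self) -> None:
        if self.stage not in self.STAGES:
            raise ValueError(f"unknown stage label {self.stage!r}")
        for role in self.mean_intensity:
            m, s = self.mean_intensity[role], self.sum_intensity.get(role)
            if m < 0 or (s is not None and s < m):
                raise ValueError(
                    f"channel {role!r}: need sum >= mean >= 0 "
                    f"(mean={m}, sum={s})"
                )

    def flatten(self) -> Dict[str, object]:
        row: Dict[str, object] = {"cell_id": self.cell_id}
        for role in sorted(self.mean_intensity):
            row[f"mean_{role}"] = self.mean_intensity[role]
        for role in sorted(self.sum_intensity):
            row[f"sum_{role}"] = self.sum_intensity[role]
        for key in sorted(self.derived):
            row[key] = self.derived[key]
        row["expression_group"] = self.expression_group
        row["stage"] = self.stage
        return row


def write_table(records: List[CellRecord], path: str | Path) -> pd.DataFrame:
    """Write cell records as CSV (one row per cell, stable column order).

    Floats are formatted with 12 significant digits; an empty record list
    yields a header-only file with the identifier columns.
    """
    if not records:
        frame = pd.DataFrame(
            columns=["cell_id", "expression_group", "stage"]
        )
        frame.to_csv(path, index=False)
        return frame
    rows = [r.flatten() for r in records]
    cols = list(rows[0])
    for row in rows[1:]:
        if list(row) != cols:
            raise SchemaError("records do not share one column schema")
    frame = pd.DataFrame(rows, columns=cols)
    frame.to_csv(path, index=False, float_format="%.12g")
    return frame


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
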