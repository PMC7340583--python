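"""Image and table I/O with explicit axis and channel conventions.

Image stacks are 4-D arrays with axes ``(channel, section, row, column)``
(C, Z, Y, X), 0-based. Channels are always addressed by *name*, never by
position; the required channels are mCherry, Citrin and CFP. Multi-channel
TIFFs written by this package carry the channel names and voxel geometry in
the image description (tifffile "shaped" metadata); OME channel names are
honored on read when present.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

REQUIRED_CHANNELS = ("mCherry", "Citrin", "CFP")

#: canonical channel order for synthetic scenes and written stacks
DEFAULT_CHANNEL_ORDER = ("mCherry", "Citrin", "CFP")

CHANNELS = REQUIRED_CHANNELS
REGIONS = ("wall", "interior")
STAT_NAMES = ("min", "max", "integral")

#: exact column schema of the per-cell table
CELL_TABLE_COLUMNS = (
    ["field_id", "label", "identity", "interior_pixels", "wall_pixels"]
    + [f"{s}_{c}_{r}" for c in CHANNELS for r in REGIONS for s in STAT_NAMES]
    + ["mean_wall_mcherry"]
)


@dataclass
class ImageField:
    """A 3-channel 3-D intensity stack with channel identities and geometry.

    Parameters
    ----------
    data
        Intensity array with axes (channel, section, row, column); finite
        and non-negative.
    channel_names
        Ordered channel names matching the channel axis; must contain
        mCherry, Citrin and CFP.
    voxel_step_z
        Axial step between optical sections, nm (acquisition default 300).
    pixel_size_xy
        Lateral pixel size, nm; optional metadata.
    """

    data: np.ndarray
    channel_names: tuple = DEFAULT_CHANNEL_ORDER
    voxel_step_z: float = 300.0
    pixel_size_xy: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"ImageField data must be 4-D (C, Z, Y, X); got ndim={self.data.ndim}"
            )
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        missing = [c for c in REQUIRED_CHANNELS if c not in self.channel_names]
        if missing:
            raise ValueError(f"missing required channel(s): {missing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_sections(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Return the (Z, Y, X) stack of the named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present in {self.channel_names}")
        return self.data[idx]


def write_field(field: ImageField, path) -> None:
    """Write an ImageField as a multi-channel TIFF (axes C,Z,Y,X).

    Channel names and voxel geometry go into the image description so that
    :func:`read_field` can map channels by name.
    """
    meta = {
        "axes": "CZYX",
        "channel_names": list(field.channel_names),
        "voxel_step_z": field.voxel_step_z,
    }
    if field.pixel_size_xy is not None:
        meta["pixel_size_xy"] = field.pixel_size_xy
    tifffile.imwrite(path, field.data, metadata=meta, photometric="minisblack")


def _ome_channel_names(ome_xml: str) -> list[str]:
    ns = {"ome": ET.fromstring(ome_xml).tag.split("}")[0].strip("{")}
    root = ET.fromstring(ome_xml)
    names = []
    for ch in root.iter(f"{{{ns['ome']}}}Channel"):
        names.append(ch.get("Name") or "")
    return names


def read_field(path) -> ImageField:
    """Read a multi-channel TIFF into an ImageField, mapping channels by name.

    Raises
    ------
    ValueError
        If the file is not 4-D (C,Z,Y,X), channel metadata is absent, or a
        required channel is missing.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.series[0].asarray()
        meta = None
        if tf.shaped_metadata:
            meta = tf.shaped_metadata[0]
        names = None
        voxel_step_z = 300.0
        pixel_size_xy = None
        if meta and "channel_names" in meta:
            names = list(meta["channel_names"])
            voxel_step_z = float(meta.get("voxel_step_z", voxel_step_z))
            if meta.get("pixel_size_xy") is not None:
                pixel_size_xy = float(meta["pixel_size_xy"])
        elif tf.ome_metadata:
            names = _ome_channel_names(tf.ome_metadata)
    if data.ndim != 4:
        raise ValueError(
            f"expected a 4-D (C, Z, Y, X) stack, got shape {data.shape}"
        )
    if not names:
        raise ValueError("no channel-name metadata found; cannot map channels")
    return ImageField(
        data=data,
        channel_names=tuple(names),
        voxel_step_z=voxel_step_z,
        pixel_size_xy=pixel_size_xy,
    )


def write_label_image(labels: np.ndarray, path) -> None:
    """Write an integer label image/volume as single-channel TIFF."""
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))


def read_label_image(path) -> np.ndarray:
    return tifffile.imread(path)


def cell_table(records: Sequence) -> pd.DataFrame:
    """Per-cell records as a DataFrame with the canonical column schema."""
    rows = [r.to_row() for r in records]
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)


def write_cell_table(records: Sequence, path) -> None:
    """Write per-cell records to CSV: one row per cell, header always present.

    An empty record list writes the header only. Floats are written at full
    round-trip precision.
    """
    cell_table(records).to_csv(path, index=False)


def read_cell_table(path) -> list:
    """Read a per-cell CSV back into CellRecord objects."""
    from .quantify import CellRecord  # local import to avoid cycle

    df = pd.read_csv(Path(path))
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    return [CellRecord.from_row(row) for _, row in df.iterrows()]
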