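"""Cell and cell-wall segmentation in the sum projection.

The pipeline collapses the Z-stack by per-pixel summation first, then
segments in 2-D: cells are thresholded from the combined cytosolic channels
(every cell carries exactly one of Citrin or CFP, so their sum is
cell-filled), and the cell wall of each cell is the peripheral band of its
mask — the pixels within ``wall_width`` (Euclidean distance) of the cell
boundary. Interior and wall partition the cell mask exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.measure import label as sk_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import clear_border, watershed
from sklearn.base import BaseEstimator

from .io import ImageField


@dataclass
class ProjectedField:
    """Per-channel 2-D sum images of a stack (axes C, Y, X)."""

    data: np.ndarray
    channel_names: tuple
    n_sections: int

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ProjectedField data must be 3-D (C, Y, X)")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel axis")

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present in {self.channel_names}")
        return self.data[idx]


@dataclass
class SegmentationParams:
    """Tunable knobs of the cell/wall segmentation.

    threshold_method
        "triangle" (default), "otsu", or "fixed" (requires
        ``fixed_threshold``), applied to the Citrin+CFP sum projection.
        The triangle method suits these images: the histogram is a dominant
        constant-background peak with a long foreground tail, and the
        projected cytosol falls off continuously at the cell rim, which
        biases Otsu's mid-slope threshold toward shrunken masks.
    min_object_pixels
        Objects smaller than this (projected pixels) are discarded.
    wall_width
        Width of the cell-wall band, pixels (Euclidean distance from the
        cell boundary).
    split_touching
        Split touching cells by distance-transform watershed.
    split_min_distance
        Minimum separation (pixels) between watershed seed maxima.
    exclude_border
        Drop cells touching the image border (their wall band is truncated).
    """

    threshold_method: str = "triangle"
    fixed_threshold: float | None = None
    min_object_pixels: int = 64
    wall_width: float = 3.0
    split_touching: bool = True
    split_min_distance: int = 10
    exclude_border: bool = True

    def __post_init__(self):
        if self.threshold_method not in ("triangle", "otsu", "fixed"):
            raise ValueError("threshold_method must be 'triangle', 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required when threshold_method='fixed'")
        if self.min_object_pixels < 1:
            raise ValueError("min_object_pixels must be >= 1")
        if self.wall_width < 1:
            raise ValueError("wall_width must be >= 1")


@dataclass
class Segmentation:
    """Cell labels plus the wall/interior partition of every cell.

    ``wall_masks[k] | interior_masks[k]`` reproduces the mask of label k
    exactly, and the two are disjoint. Cells whose interior is empty at the
    requested wall width are recorded in ``degenerate`` and excluded from
    measurement.
    """

    cell_labels: np.ndarray
    wall_masks: Dict[int, np.ndarray]
    interior_masks: Dict[int, np.ndarray]
    degenerate: set = dc_field(default_factory=set)
    params: SegmentationParams | None = None

    @property
    def labels(self) -> list:
        return sorted(self.wall_masks)

    def measurable_labels(self) -> list:
        return [k for k in self.labels if k not in self.degenerate]

    def cell_mask(self, label: int) -> np.ndarray:
        return self.wall_masks[label] | self.interior_masks[label]


def sum_project(field: ImageField) -> ProjectedField:
    """Sum all optical sections per channel.

    Accumulation is in float64 so integer stacks cannot saturate.
    """
    if field.n_sections < 1:
        raise ValueError("field must have at least one section")
    proj = field.data.astype(np.float64, copy=False).sum(axis=1)
    return ProjectedField(
        data=proj, channel_names=field.channel_names, n_sections=field.n_sections
    )


def boundary_band(mask: np.ndarray, width: float) -> tuple[np.ndarray, np.ndarray]:
    """Split a binary mask into (band, interior) by Euclidean distance.

    The band holds the pixels of ``mask`` whose Euclidean distance to the
    nearest background pixel is <= ``width``; the interior is the rest.
    Distance-based (not structuring-element) erosion keeps the band width
    rotation invariant.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    mask = np.asarray(mask, dtype=bool)
    dist = ndi.distance_transform_edt(mask)
    interior = dist > width
    band = mask & ~interior
    return band, interior


def _relabel_scan_order(labels: np.ndarray) -> np.ndarray:
    """Relabel consecutively from 1 in raster-scan (top-left first) order."""
    flat = labels.ravel()
    vals, first = np.unique(flat, return_index=True)
    keep = vals != 0
    vals, first = vals[keep], first[keep]
    order = np.argsort(first)
    mapping = np.zeros(int(vals.max()) + 1 if vals.size else 1, dtype=np.int32)
    for new, old in enumerate(vals[order], start=1):
        mapping[old] = new
    return mapping[labels]


def segment_cells(proj: ProjectedField, params: SegmentationParams | None = None) -> np.ndarray:
    """Segment yeast cells from the cytosolic channels.

    Foreground is a threshold of the Citrin+CFP sum projection, hole-filled;
    small objects are removed; touching cells are optionally split by
    distance-transform watershed; border-touching cells optionally removed.
    Returns a 2-D int32 label image with consecutive labels assigned in
    raster-scan order (deterministic). An all-background image yields an
    empty labeling, not an error.
    """
    params = params or SegmentationParams()
    cyto = proj.channel("Citrin").astype(np.float64) + proj.channel("CFP")
    if cyto.max() == cyto.min():
        return np.zeros(cyto.shape, dtype=np.int32)
    if params.threshold_method == "triangle":
        thr = threshold_triangle(cyto)
    elif params.threshold_method == "otsu":
        thr = threshold_otsu(cyto)
    else:
        thr = params.fixed_threshold
    fg = cyto > thr
    fg = ndi.binary_fill_holes(fg)
    fg = remove_small_objects(fg, max_size=params.min_object_pixels - 1)
    if not fg.any():
        return np.zeros(cyto.shape, dtype=np.int32)

    if params.split_touching:
        dist = ndi.distance_transform_edt(fg)
        coords = peak_local_max(
            dist,
            min_distance=params.split_min_distance,
            labels=sk_label(fg),
            exclude_border=False,
        )
        if len(coords) == 0:
            labels = sk_label(fg).astype(np.int32)
        else:
            # deterministic seed order: raster scan of the peak coordinates
            order = np.lexsort((coords[:, 1], coords[:, 0]))
            markers = np.zeros(fg.shape, dtype=np.int32)
            for i, (r, c) in enumerate(coords[order], start=1):
                markers[r, c] = i
            labels = watershed(-dist, markers, mask=fg).astype(np.int32)
    else:
        labels = sk_label(fg).astype(np.int32)

    if params.exclude_border:
        labels = clear_border(labels)
    # size filter again: watershed fragments / border clearing may leave crumbs
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < params.min_object_pixels)
    labels[np.isin(labels, small[small > 0])] = 0
    return _relabel_scan_order(labels)


def segment_wall(labels: np.ndarray, wall_width: float = 3.0,
                 params: SegmentationParams | None = None) -> Segmentation:
    """Carve each cell into wall band and interior.

    The wall of cell k is the set of its pixels within ``wall_width``
    (Euclidean) of the cell boundary — pixels of neighbouring cells count as
    outside, so touching cells get a wall along their shared edge. Cells
    whose interior erodes away entirely are flagged degenerate.
    """
    if wall_width <= 0:
        raise ValueError("wall_width must be positive")
    labels = np.asarray(labels)
    wall_masks: Dict[int, np.ndarray] = {}
    interior_masks: Dict[int, np.ndarray] = {}
    degenerate: set = set()
    objects = ndi.find_objects(labels)
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        pad = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, n))
            for s, n in zip(sl, labels.shape)
        )
        sub = labels[pad] == k
        band, interior = boundary_band(sub, wall_width)
        wall = np.zeros(labels.shape, dtype=bool)
        inter = np.zeros(labels.shape, dtype=bool)
        wall[pad] = band
        inter[pad] = interior
        wall_masks[k] = wall
        interior_masks[k] = inter
        if not interior.any():
            degenerate.add(k)
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} cell(s) degenerate at wall_width={wall_width}: "
            f"{sorted(degenerate)}",
            stacklevel=2,
        )
    return Segmentation(
        cell_labels=labels,
        wall_masks=wall_masks,
        interior_masks=interior_masks,
        degenerate=degenerate,
        params=params,
    )


class CellSegmenter(BaseEstimator):
    """Stateless transformer: ImageField -> Segmentation.

    Runs sum-projection, cell segmentation and wall segmentation with the
    held parameters. Composes with sklearn pipelines (``fit`` is a no-op).
    """

    def __init__(self, threshold_method="triangle", fixed_threshold=None,
                 min_object_pixels=64, wall_width=3.0, split_touching=True,
                 split_min_distance=10, exclude_border=True):
        self.threshold_method = threshold_method
        self.fixed_threshold = fixed_threshold
        self.min_object_pixels = min_object_pixels
        self.wall_width = wall_width
        self.split_touching = split_touching
        self.split_min_distance = split_min_distance
        self.exclude_border = exclude_border

    def _params(self) -> SegmentationParams:
        return SegmentationParams(
            threshold_method=self.threshold_method,
            fixed_threshold=self.fixed_threshold,
            min_object_pixels=self.min_object_pixels,
            wall_width=self.wall_width,
            split_touching=self.split_touching,
            split_min_distance=self.split_min_distance,
            exclude_border=self.exclude_border,
        )

    def fit(self, X=None, y=None):
        return self

    def segment(self, field: ImageField) -> Segmentation:
        params = self._params()
        proj = sum_project(field)
        labels = segment_cells(proj, params)
        return segment_wall(labels, params.wall_width, params=params)

    def transform(self, X: ImageField) -> Segmentation:
        return self.segment(X)
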