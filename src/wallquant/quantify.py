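"""Per-cell intensity accounting, volume filtering and strain classification.

For every segmented cell the pipeline records pixel counts and the min, max
and integral intensity of each channel (mCherry, Citrin, CFP) separately in
the cell wall and the cell interior. Cells are kept only if
their interior area lies in the empirically assigned 2400–55,000 pixel
window, and strain identity is assigned from the maximal cytosolic
intensity in the interior: the reference strain carries cytosolic Citrin,
tester strains cytosolic CFP. The per-cell statistic of interest is the
mean wall mCherry: integral mCherry in the wall divided by wall pixel count.

Classification thresholds (200 ADU) refer to fluorescence above background.
``quantify_field`` therefore estimates a per-channel background level from
the cell-free pixels of the sum projection and subtracts it from the
interior maxima before thresholding; the recorded per-cell intensities stay
raw. This keeps classification invariant to the camera offset, which a
summed raw stack multiplies by the section count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .io import CHANNELS, REGIONS, cell_table
from .segmentation import (
    ProjectedField,
    Segmentation,
    SegmentationParams,
    segment_cells,
    segment_wall,
    sum_project,
)

logger = logging.getLogger(__name__)

IDENTITIES = ("reference", "tester", "unclassified")


@dataclass
class RegionStats:
    """Min/max/integral intensity of one channel over one pixel region."""

    min: float
    max: float
    integral: float

    def __post_init__(self):
        if self.min > self.max:
            raise ValueError("min must not exceed max")


@dataclass
class CellRecord:
    """One segmented cell's complete measurement record.

    ``stats[channel][region]`` holds RegionStats for channel in
    (mCherry, Citrin, CFP) and region in (wall, interior).
    """

    field_id: str
    label: int
    interior_pixels: int
    wall_pixels: int
    stats: Dict[str, Dict[str, RegionStats]]
    identity: str = "unclassified"

    def __post_init__(self):
        if self.identity not in IDENTITIES:
            raise ValueError(f"identity must be one of {IDENTITIES}")
        if self.wall_pixels < 1 or self.interior_pixels < 1:
            raise ValueError("wall and interior must each contain pixels")
        for c in CHANNELS:
            for r, n in (("wall", self.wall_pixels), ("interior", self.interior_pixels)):
                s = self.stats[c][r]
                lo, hi = s.min * n, s.max * n
                if not (lo - 1e-6 <= s.integral <= hi + 1e-6):
                    raise ValueError(
                        f"integral of {c}/{r} inconsistent with min/max and pixel count"
                    )

    @property
    def mean_wall_mcherry(self) -> float:
        return self.stats["mCherry"]["wall"].integral / self.wall_pixels

    def to_row(self) -> dict:
        row = {
            "field_id": self.field_id,
            "label": self.label,
            "identity": self.identity,
            "interior_pixels": self.interior_pixels,
            "wall_pixels": self.wall_pixels,
        }
        for c in CHANNELS:
            for r in REGIONS:
                s = self.stats[c][r]
                row[f"min_{c}_{r}"] = s.min
                row[f"max_{c}_{r}"] = s.max
                row[f"integral_{c}_{r}"] = s.integral
        row["mean_wall_mcherry"] = self.mean_wall_mcherry
        return row

    @classmethod
    def from_row(cls, row) -> "CellRecord":
        stats = {
            c: {
                r: RegionStats(
                    min=float(row[f"min_{c}_{r}"]),
                    max=float(row[f"max_{c}_{r}"]),
                    integral=float(row[f"integral_{c}_{r}"]),
                )
                for r in REGIONS
            }
            for c in CHANNELS
        }
        return cls(
            field_id=str(row["field_id"]),
            label=int(row["label"]),
            interior_pixels=int(row["interior_pixels"]),
            wall_pixels=int(row["wall_pixels"]),
            stats=stats,
            identity=str(row["identity"]),
        )


@dataclass
class ClassificationParams:
    """Volume filter bounds and identity thresholds (summed-projection ADU).

    Defaults: interior area window [2400, 55000] pixels
    (closed interval) and 200-ADU cytosolic thresholds. ``channel_background``
    maps channel name to a background level subtracted from interior maxima
    before thresholding (filled in automatically by ``quantify_field``).
    ``swap_identity_channels`` swaps the channel-to-identity mapping
    (reference=CFP-high instead of Citrin-high).
    """

    cfp_threshold: float = 200.0
    citrin_threshold: float = 200.0
    volume_min: int = 2400
    volume_max: int = 55000
    swap_identity_channels: bool = False
    channel_background: Dict[str, float] | None = None

    def __post_init__(self):
        if self.cfp_threshold <= 0 or self.citrin_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not self.volume_min < self.volume_max:
            raise ValueError("volume_min must be < volume_max")


def measure_cell(proj: ProjectedField, seg: Segmentation, label: int) -> CellRecord:
    """Exact per-channel min/max/integral over a cell's wall and interior.

    Accumulates in float64; identity is left "unclassified". Raises on
    labels missing from the segmentation or flagged degenerate.
    """
    if label not in seg.wall_masks:
        raise KeyError(f"label {label} not present in segmentation")
    if label in seg.degenerate:
        raise ValueError(f"label {label} is degenerate (empty interior)")
    wall = seg.wall_masks[label]
    interior = seg.interior_masks[label]
    stats: Dict[str, Dict[str, RegionStats]] = {}
    for c in CHANNELS:
        img = proj.channel(c).astype(np.float64, copy=False)
        stats[c] = {}
        for rname, mask in (("wall", wall), ("interior", interior)):
            vals = img[mask]
            stats[c][rname] = RegionStats(
                min=float(vals.min()), max=float(vals.max()), integral=float(vals.sum())
            )
    return CellRecord(
        field_id="",
        label=int(label),
        interior_pixels=int(interior.sum()),
        wall_pixels=int(wall.sum()),
        stats=stats,
    )


def filter_by_volume(
    records: Sequence[CellRecord], params: ClassificationParams | None = None
) -> List[CellRecord]:
    """Keep cells whose interior area lies in [volume_min, volume_max].

    The interval is closed at both ends; order is preserved and the number
    of removed cells is logged.
    """
    params = params or ClassificationParams()
    kept = [
        r for r in records if params.volume_min <= r.interior_pixels <= params.volume_max
    ]
    removed = len(records) - len(kept)
    if removed:
        logger.info(
            "volume filter removed %d of %d cells (window [%d, %d] px)",
            removed, len(records), params.volume_min, params.volume_max,
        )
    return kept


def classify_identity(
    record: CellRecord, params: ClassificationParams | None = None
) -> str:
    """Assign strain identity from interior cytosolic maxima.

    reference: Citrin above threshold and CFP below; tester: CFP above and
    Citrin below; anything else (including values exactly at a threshold,
    both inequalities being strict) is "unclassified". Background levels in
    ``params.channel_background`` are subtracted from the maxima first.
    """
    params = params or ClassificationParams()
    bg = params.channel_background or {}
    cfp = record.stats["CFP"]["interior"].max - bg.get("CFP", 0.0)
    citrin = record.stats["Citrin"]["interior"].max - bg.get("Citrin", 0.0)
    citrin_high = citrin > params.citrin_threshold and cfp < params.cfp_threshold
    cfp_high = cfp > params.cfp_threshold and citrin < params.citrin_threshold
    if citrin_high:
        return "tester" if params.swap_identity_channels else "reference"
    if cfp_high:
        return "reference" if params.swap_identity_channels else "tester"
    return "unclassified"


def estimate_channel_background(proj: ProjectedField, labels: np.ndarray) -> Dict[str, float]:
    """Median projected intensity per channel over cell-free pixels."""
    background = labels == 0
    if not background.any():
        warnings.warn("no background pixels; background set to 0", stacklevel=2)
        return {c: 0.0 for c in CHANNELS}
    return {c: float(np.median(proj.channel(c)[background])) for c in CHANNELS}


def quantify_field(
    field,
    seg_params: SegmentationParams | None = None,
    class_params: ClassificationParams | None = None,
    field_id: str = "field0",
) -> List[CellRecord]:
    """Full per-field pipeline: project, segment, measure, filter, classify.

    Unclassified cells are retained in the output (flagged) so their
    exclusion from downstream statistics is auditable.
    """
    seg_params = seg_params or SegmentationParams()
    class_params = class_params or ClassificationParams()
    try:
        proj = sum_project(field)
    except Exception as e:
        raise RuntimeError(f"sum-projection stage failed: {e}") from e
    try:
        labels = segment_cells(proj, seg_params)
        seg = segment_wall(labels, seg_params.wall_width, params=seg_params)
    except Exception as e:
        raise RuntimeError(f"segmentation stage failed: {e}") from e
    if class_params.channel_background is None:
        class_params = replace(
            class_params, channel_background=estimate_channel_background(proj, labels)
        )
    records = []
    try:
        for k in seg.measurable_labels():
            rec = measure_cell(proj, seg, k)
            rec.field_id = field_id
            records.append(rec)
    except Exception as e:
        raise RuntimeError(f"measurement stage failed: {e}") from e
    records = filter_by_volume(records, class_params)
    for rec in records:
        rec.identity = classify_identity(rec, class_params)
    return records


class WallQuantifier(BaseEstimator):
    """Stateless transformer: ImageField -> per-cell measurement table.

    Bundles the segmentation and classification parameters behind one
    sklearn-style estimator; ``transform`` returns the per-cell DataFrame
    (canonical cell-table schema), ``quantify`` the CellRecord list.
    """

    def __init__(self, threshold_method="triangle", fixed_threshold=None,
                 min_object_pixels=64, wall_width=3.0, split_touching=True,
                 split_min_distance=10, exclude_border=True,
                 cfp_threshold=200.0, citrin_threshold=200.0,
                 volume_min=2400, volume_max=55000,
                 swap_identity_channels=False, field_id="field0"):
        self.threshold_method = threshold_method
        self.fixed_threshold = fixed_threshold
        self.min_object_pixels = min_object_pixels
        self.wall_width = wall_width
        self.split_touching = split_touching
        self.split_min_distance = split_min_distance
        self.exclude_border = exclude_border
        self.cfp_threshold = cfp_threshold
        self.citrin_threshold = citrin_threshold
        self.volume_min = volume_min
        self.volume_max = volume_max
        self.swap_identity_channels = swap_identity_channels
        self.field_id = field_id

    def fit(self, X=None, y=None):
        return self

    def quantify(self, field) -> List[CellRecord]:
        seg_params = SegmentationParams(
            threshold_method=self.threshold_method,
            fixed_threshold=self.fixed_threshold,
            min_object_pixels=self.min_object_pixels,
            wall_width=self.wall_width,
            split_touching=self.split_touching,
            split_min_distance=self.split_min_distance,
            exclude_border=self.exclude_border,
        )
        class_params = ClassificationParams(
            cfp_threshold=self.cfp_threshold,
            citrin_threshold=self.citrin_threshold,
            volume_min=self.volume_min,
            volume_max=self.volume_max,
            swap_identity_channels=self.swap_identity_channels,
        )
        return quantify_field(
            field, seg_params, class_params, field_id=self.field_id
        )

    def transform(self, X):
        return cell_table(self.quantify(X))
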