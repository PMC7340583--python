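"""Intensity accounting, volume filter, identity classification, full pipeline."""

import numpy as np
import pytest

from wallquant import (
    CellSpec,
    ClassificationParams,
    SceneSpec,
    SegmentationParams,
    WallQuantifier,
    classify_identity,
    filter_by_volume,
    generate_field,
    measure_cell,
    quantify_field,
    segment_cells,
    segment_wall,
    sum_project,
)
from wallquant.quantify import CellRecord, RegionStats
from wallquant.segmentation import ProjectedField, Segmentation

from conftest import match_labels


def make_record(max_cfp=100.0, max_citrin=100.0, interior_pixels=3000,
                wall_pixels=500, identity="unclassified"):
    """Minimal CellRecord with prescribed interior maxima."""
    stats = {}
    for c, mx in (("mCherry", 50.0), ("Citrin", max_citrin), ("CFP", max_cfp)):
        stats[c] = {
            "wall": RegionStats(min=0.0, max=50.0, integral=25.0 * wall_pixels),
            "interior": RegionStats(min=0.0, max=mx, integral=mx / 2 * interior_pixels),
        }
    return CellRecord(field_id="f", label=1, interior_pixels=interior_pixels,
                      wall_pixels=wall_pixels, stats=stats, identity=identity)


class TestMeasureCell:
    def constant_setup(self, wall_value=100.0, interior_value=40.0):
        img = np.full((30, 30), interior_value)
        wall = np.zeros((30, 30), dtype=bool)
        interior = np.zeros((30, 30), dtype=bool)
        yy, xx = np.indices((30, 30))
        r = np.hypot(yy - 15, xx - 15)
        wall[(r <= 12) & (r > 9)] = True
        interior[r <= 9] = True
        img[wall] = wall_value
        proj = ProjectedField(data=np.stack([img] * 3),
                              channel_names=("mCherry", "Citrin", "CFP"),
                              n_sections=1)
        labels = (wall | interior).astype(np.int32)
        seg = Segmentation(cell_labels=labels, wall_masks={1: wall},
                           interior_masks={1: interior})
        return proj, seg, wall.sum(), interior.sum()

    def test_constant_region_identity(self):
        proj, seg, n_wall, n_int = self.constant_setup(wall_value=100.0)
        rec = measure_cell(proj, seg, 1)
        s = rec.stats["mCherry"]["wall"]
        assert (s.min, s.max) == (100.0, 100.0)
        assert s.integral == 100.0 * n_wall
        assert rec.mean_wall_mcherry == 100.0
        assert rec.stats["CFP"]["interior"].integral == 40.0 * n_int

    def test_matches_naive_per_pixel_loop(self, noisy_two_cell_field):
        field, _ = noisy_two_cell_field
        proj = sum_project(field)
        labels = segment_cells(proj)
        seg = segment_wall(labels, wall_width=2)
        for k in seg.measurable_labels():
            rec = measure_cell(proj, seg, k)
            for c in ("mCherry", "Citrin", "CFP"):
                img = proj.channel(c)
                for rname, mask in (("wall", seg.wall_masks[k]),
                                    ("interior", seg.interior_masks[k])):
                    vals = [img[y, x] for y, x in np.argwhere(mask)]
                    s = rec.stats[c][rname]
                    assert s.min == min(vals)
                    assert s.max == max(vals)
                    assert s.integral == pytest.approx(sum(vals), rel=1e-12)

    def test_accounting_identity(self, two_cell_field):
        """wall + interior integrals equal the integral over the whole cell."""
        field, _ = two_cell_field
        proj = sum_project(field)
        labels = segment_cells(proj)
        seg = segment_wall(labels, wall_width=3)
        for k in seg.measurable_labels():
            rec = measure_cell(proj, seg, k)
            for c in ("mCherry", "Citrin", "CFP"):
                whole = proj.channel(c)[labels == k].sum()
                total = rec.stats[c]["wall"].integral + rec.stats[c]["interior"].integral
                assert total == pytest.approx(whole, rel=1e-12)

    def test_crescent_wall_integral_matches_voxel_count(self):
        """Projected mCherry over a crescent cell accounts for every wall voxel."""
        cell = CellSpec(center=(10, 24, 24), radii=(7, 16, 16), identity="tester",
                        cytosol_intensity=400, wall_intensity=250, wall_thickness=2,
                        localization="crescent", crescent_axis=(0, 0, 1),
                        crescent_halfangle=90.0)
        spec = SceneSpec(image_shape=(21, 49, 49), cells=[cell], camera_offset=100,
                         gaussian_sd=0, poisson_scale=0)
        field, gt = generate_field(spec)
        proj = sum_project(field)
        footprint = (gt.label_volume == 1).any(axis=0)
        n_wall_voxels = int(gt.wall_mask_volume.sum())
        total_mcherry = proj.channel("mCherry")[footprint].sum()
        offset_share = 100 * field.n_sections * footprint.sum()
        assert total_mcherry - offset_share == pytest.approx(250 * n_wall_voxels)

    def test_degenerate_label_raises_with_name(self):
        proj, seg, *_ = self.constant_setup()
        seg.degenerate.add(1)
        with pytest.raises(ValueError, match="1"):
            measure_cell(proj, seg, 1)
        with pytest.raises(KeyError):
            measure_cell(proj, seg, 99)


class TestVolumeFilter:
    @pytest.mark.parametrize("pixels,kept", [
        (2399, False), (2400, True), (55_000, True), (55_001, False),
    ])
    def test_window_boundaries_closed_interval(self, pixels, kept):
        records = [make_record(interior_pixels=pixels)]
        assert (len(filter_by_volume(records, ClassificationParams())) == 1) is kept

    def test_empty_input(self):
        assert filter_by_volume([], ClassificationParams()) == []

    def test_idempotent_and_order_preserving(self):
        records = [make_record(interior_pixels=n)
                   for n in (100, 2400, 9000, 55_000, 60_000)]
        once = filter_by_volume(records, ClassificationParams())
        assert [r.interior_pixels for r in once] == [2400, 9000, 55_000]
        assert filter_by_volume(once, ClassificationParams()) == once


class TestClassifyIdentity:
    @pytest.mark.parametrize("cfp,citrin,expected", [
        (300, 100, "tester"),
        (100, 300, "reference"),
        (300, 300, "unclassified"),  # both bright: ambiguous
        (100, 100, "unclassified"),
        (200, 100, "unclassified"),  # exactly at threshold: strict inequality
        (100, 200, "unclassified"),
    ])
    def test_threshold_logic(self, cfp, citrin, expected):
        rec = make_record(max_cfp=cfp, max_citrin=citrin)
        assert classify_identity(rec, ClassificationParams()) == expected

    def test_channel_swap_symmetry(self):
        for cfp, citrin in [(300, 100), (100, 300), (250, 250), (10, 10)]:
            rec = make_record(max_cfp=cfp, max_citrin=citrin)
            swapped = make_record(max_cfp=citrin, max_citrin=cfp)
            a = classify_identity(rec, ClassificationParams())
            b = classify_identity(swapped, ClassificationParams())
            flip = {"tester": "reference", "reference": "tester",
                    "unclassified": "unclassified"}
            assert b == flip[a]

    def test_swap_identity_channels_restores_literal_reading(self):
        rec = make_record(max_cfp=300, max_citrin=100)
        assert classify_identity(
            rec, ClassificationParams(swap_identity_channels=True)
        ) == "reference"

    def test_background_correction(self):
        # offset-inflated maxima classify correctly once background is removed
        rec = make_record(max_cfp=2800 + 400, max_citrin=2800 + 50)
        params = ClassificationParams(
            channel_background={"CFP": 2800.0, "Citrin": 2800.0})
        assert classify_identity(rec, params) == "tester"
        assert classify_identity(rec, ClassificationParams()) == "unclassified"


class TestQuantifyField:
    def six_cell_spec(self, offset=100.0):
        cells = []
        for i, (cy, cx) in enumerate([(60, 75), (60, 225), (150, 75),
                                      (150, 225), (240, 75), (240, 225)]):
            identity = "reference" if i % 2 == 0 else "tester"
            cells.append(CellSpec(
                center=(6, cy, cx), radii=(5, 34, 34), identity=identity,
                cytosol_intensity=400,
                wall_intensity=0.0 if identity == "reference" else 400.0,
                wall_thickness=2,
            ))
        return SceneSpec(image_shape=(12, 300, 300), cells=cells,
                         camera_offset=offset, gaussian_sd=0, poisson_scale=0)

    def test_end_to_end_identities_and_means(self):
        field, gt = generate_field(self.six_cell_spec())
        records = quantify_field(field, SegmentationParams(wall_width=2))
        assert len(records) == 6
        labels = segment_cells(sum_project(field), SegmentationParams(wall_width=2))
        mapping = match_labels(labels, gt)
        by_label = {r.label: r for r in records}
        for rec_label, true_label in mapping.items():
            rec = by_label[rec_label]
            assert rec.identity == gt.identity_map[true_label]
            truth = gt.true_mean_wall_mcherry[true_label]
            assert abs(rec.mean_wall_mcherry - truth) / truth < 0.05

    def test_volume_filter_inside_pipeline(self):
        field, _ = generate_field(self.six_cell_spec())
        records = quantify_field(
            field,
            SegmentationParams(wall_width=2),
            ClassificationParams(volume_min=100, volume_max=2000),
        )
        assert records == []  # interiors ~2850 px exceed the narrowed window

    def test_deterministic(self):
        field, _ = generate_field(self.six_cell_spec())
        r1 = quantify_field(field, SegmentationParams(wall_width=2))
        r2 = quantify_field(field, SegmentationParams(wall_width=2))
        assert r1 == r2

    def test_wall_quantifier_transform_schema(self):
        from wallquant.io import CELL_TABLE_COLUMNS

        field, _ = generate_field(self.six_cell_spec())
        df = WallQuantifier(wall_width=2).fit().transform(field)
        assert list(df.columns) == CELL_TABLE_COLUMNS
        assert len(df) == 6
        assert set(df["identity"]) == {"reference", "tester"}

    def test_bias_shrinks_with_noise(self):
        """Measurement error decreases monotonically as read noise drops."""
        errors = []
        for sd in (30.0, 8.0, 0.0):
            spec = self.six_cell_spec()
            spec = SceneSpec(image_shape=spec.image_shape, cells=spec.cells,
                             camera_offset=100, gaussian_sd=sd, poisson_scale=0,
                             seed=5)
            field, gt = generate_field(spec)
            records = quantify_field(field, SegmentationParams(wall_width=2))
            labels = segment_cells(sum_project(field), SegmentationParams(wall_width=2))
            mapping = match_labels(labels, gt)
            by_label = {r.label: r for r in records}
            errs = [
                abs(by_label[rl].mean_wall_mcherry - gt.true_mean_wall_mcherry[tl])
                for rl, tl in mapping.items() if rl in by_label
            ]
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]
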