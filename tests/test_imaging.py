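"""Particle-sizing pipeline: crop, normalization, segmentation, border
exclusion, calibration, measurement, and size summaries."""

import numpy as np
import pandas as pd
import pytest

from capmetrics import imaging
from capmetrics.errors import EmptyTableError, SegmentationError
from capmetrics.imaging import (
    ImagingConfig,
    Micrograph,
    Scale,
    calibrate_scale,
    crop_databar,
    exclude_border_particles,
    measure_particles,
    normalize_contrast,
    render_overlay,
    segment_instances,
    summarize_sizes,
)
from capmetrics.synthetic import MicrographSimParams, simulate_micrograph


def _table(diams_um):
    return pd.DataFrame(
        {
            "label": range(1, len(diams_um) + 1),
            "contour": [None] * len(diams_um),
            "diameter_px": diams_um,
            "diameter_um": diams_um,
            "excluded_reason": ["none"] * len(diams_um),
        }
    )


class TestCrop:
    def test_removes_databar_rows(self):
        img = Micrograph(np.zeros((1089, 1024), dtype=np.uint8), databar_height=65)
        out = crop_databar(img, 65)
        assert out.shape == (1024, 1024)
        assert out.databar_height == 0

    def test_top_rows_unchanged_and_metadata_preserved(self):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 256, size=(100, 80)).astype(np.uint8)
        img = Micrograph(px, databar_height=20, scalebar_px=111, scalebar_um=5.0)
        out = crop_databar(img, 20)
        assert np.array_equal(out.pixels, px[:80])
        assert out.scalebar_px == 111 and out.scalebar_um == 5.0

    def test_zero_crop_identity(self):
        px = np.arange(12, dtype=np.uint8).reshape(3, 4)
        img = Micrograph(px, databar_height=0)
        assert np.array_equal(crop_databar(img, 0).pixels, px)

    def test_crop_whole_image_rejected(self):
        img = Micrograph(np.zeros((10, 10), dtype=np.uint8), databar_height=0)
        with pytest.raises(ValueError):
            crop_databar(img, 10)


class TestNormalize:
    def test_affine_endpoints_and_midpoint(self):
        px = np.array([[10, 15], [20, 10]], dtype=np.uint8)
        out = normalize_contrast(Micrograph(px, databar_height=0))
        assert out.pixels[0, 0] == 0
        assert out.pixels[1, 0] == 255
        assert out.pixels[0, 1] == 128  # 127.5 rounds half-even to 128

    def test_constant_image_maps_to_zeros_with_warning(self):
        px = np.full((5, 5), 77, dtype=np.uint8)
        with pytest.warns(UserWarning):
            out = normalize_contrast(Micrograph(px, databar_height=0))
        assert np.all(out.pixels == 0)

    def test_full_range_image_unchanged(self):
        px = np.linspace(0, 255, 256).astype(np.uint8).reshape(16, 16)
        px[0, 0], px[-1, -1] = 0, 255
        out = normalize_contrast(Micrograph(px, databar_height=0))
        assert np.array_equal(out.pixels, px)


class TestCalibrateScale:
    def test_published_scalebar_ratio(self):
        s = calibrate_scale(229, 20.0)
        assert s.um_per_px == pytest.approx(0.087336, abs=5e-7)

    def test_identity_scale(self):
        assert calibrate_scale(100, 100.0).um_per_px == 1.0

    def test_base_object_physical_size(self):
        s = calibrate_scale(229, 20.0)
        assert 30 * s.um_per_px == pytest.approx(2.620, abs=5e-4)

    @pytest.mark.parametrize("px,um", [(0, 20), (229, 0), (-1, 20)])
    def test_nonpositive_inputs_rejected(self, px, um):
        with pytest.raises(ValueError):
            calibrate_scale(px, um)


class TestSegmentation:
    def test_fifty_disjoint_disks_give_fifty_labels(self):
        p = MicrographSimParams(
            n_particles=50, image_width=1024, image_height=1024,
            allow_border=False, max_overlap_fraction=0.0, seed=1,
        )
        img, truth = simulate_micrograph(p)
        img = normalize_contrast(crop_databar(img))
        mask = segment_instances(img)
        assert mask.max() == 50

    def test_blank_image_zero_labels(self):
        img = Micrograph(np.zeros((64, 64), dtype=np.uint8), databar_height=0)
        mask = segment_instances(img)
        assert mask.max() == 0

    def test_overlapping_pair_split_by_watershed(self):
        p = MicrographSimParams(
            n_particles=2, image_width=256, image_height=256,
            allow_border=False, max_overlap_fraction=0.10, noise_sd=4.0,
            median_um=4.5, sigma_log=0.1, seed=3,
        )
        img, truth = simulate_micrograph(p)
        img = normalize_contrast(crop_databar(img))
        mask = segment_instances(img)
        assert mask.max() == 2
        # each truth center falls in its own label
        labels = {
            mask[int(round(r.row)), int(round(r.col))] for r in truth.itertuples()
        }
        assert labels == {1, 2}

    def test_unknown_backend_named_in_error(self):
        img = Micrograph(np.zeros((8, 8), dtype=np.uint8), databar_height=0)
        with pytest.raises(SegmentationError, match="nonesuch"):
            segment_instances(img, backend="nonesuch")

    def test_backend_failure_propagated_with_identity(self):
        def broken(arr, cfg):
            raise RuntimeError("boom")

        img = Micrograph(np.zeros((8, 8), dtype=np.uint8), databar_height=0)
        with pytest.raises(SegmentationError, match="broken"):
            segment_instances(img, backend=broken)

    def test_min_area_filter_compacts_labels(self):
        def speckles(arr, cfg):
            m = np.zeros_like(arr, dtype=np.int32)
            m[0:20, 0:20] = 1       # big
            m[30, 30] = 2           # single-pixel speck
            m[40:60, 40:60] = 3     # big
            return m

        img = Micrograph(np.zeros((64, 64), dtype=np.uint8), databar_height=0)
        mask = segment_instances(img, ImagingConfig(min_area_px=9), backend=speckles)
        assert sorted(np.unique(mask)) == [0, 1, 2]


class TestBorderExclusion:
    def test_interior_disk_retained(self):
        m = np.zeros((20, 20), dtype=np.int32)
        m[5:10, 5:10] = 1
        flags = exclude_border_particles(m)
        assert not flags.touches_border.iloc[0]

    def test_single_pixel_on_edge_excluded(self):
        m = np.zeros((20, 20), dtype=np.int32)
        m[5:10, 0:5] = 1  # touches column 0
        flags = exclude_border_particles(m)
        assert flags.touches_border.iloc[0]

    def test_simulated_interior_count_matches_truth(self):
        p = MicrographSimParams(
            n_particles=60, image_width=800, image_height=800,
            allow_border=True, seed=4,
        )
        img, truth = simulate_micrograph(p)
        table, summary, mask = imaging.size_micrograph(img)
        assert summary.valid_n == int((~truth.touches_border).sum())


class TestMeasure:
    def test_centered_disk_diameter_recovered(self):
        m = np.zeros((128, 128), dtype=np.int32)
        yy, xx = np.mgrid[0:128, 0:128]
        m[np.hypot(yy - 64, xx - 64) <= 23] = 1  # 46 px diameter
        scale = calibrate_scale(229, 20.0)
        table = measure_particles(m, scale)
        px_equiv = scale.um_per_px
        assert table.diameter_um.iloc[0] == pytest.approx(4.017, abs=px_equiv)

    def test_empty_mask_empty_table(self):
        t = measure_particles(np.zeros((16, 16), dtype=np.int32), Scale(1.0))
        assert t.empty

    def test_occluded_disk_mec_recovers_true_diameter(self):
        """A disk with ~30% of its area hidden behind a neighbor still gets
        its full diameter from the minimum enclosing circle (within 3%)."""
        H = W = 220
        yy, xx = np.mgrid[0:H, 0:W]
        r = 40.0
        d1 = np.hypot(yy - 110, xx - 70) <= r
        d2 = np.hypot(yy - 110, xx - 70 - 1.15 * r) <= r
        mask = np.zeros((H, W), dtype=np.int32)
        mask[d2] = 2
        mask[d1 & ~d2] = 1
        hidden = 1 - (mask == 1).sum() / d1.sum()
        assert 0.25 < hidden < 0.35
        table = measure_particles(mask, Scale(1.0))
        meas = table.loc[table.label == 1, "diameter_px"].iloc[0]
        assert abs(meas - 2 * r) / (2 * r) < 0.03

    def test_border_rows_carry_no_um_diameter(self):
        m = np.zeros((20, 20), dtype=np.int32)
        m[0:5, 5:10] = 1
        m[10:15, 5:10] = 2
        table = measure_particles(m, Scale(1.0))
        border_row = table[table.label == 1].iloc[0]
        assert border_row.excluded_reason == "border"
        assert np.isnan(border_row.diameter_um)
        kept = table[table.label == 2].iloc[0]
        assert kept.excluded_reason == "none"
        assert np.isfinite(kept.diameter_um)

    def test_scale_linearity(self):
        m = np.zeros((64, 64), dtype=np.int32)
        yy, xx = np.mgrid[0:64, 0:64]
        m[np.hypot(yy - 32, xx - 32) <= 10] = 1
        t1 = measure_particles(m, Scale(1.0))
        t2 = measure_particles(m, Scale(2.0))
        assert t2.diameter_um.iloc[0] == pytest.approx(2 * t1.diameter_um.iloc[0])


class TestSummary:
    def test_symmetric_set(self):
        s = summarize_sizes(_table([2.0, 4.0, 6.0]))
        assert s.mean_um == pytest.approx(4.0)
        assert s.d50_um == pytest.approx(4.0)
        assert s.valid_n == 3

    def test_linear_interpolation_percentiles(self):
        s = summarize_sizes(_table(list(range(1, 10))))
        assert s.d10_um == pytest.approx(1.8)
        assert s.d90_um == pytest.approx(8.2)

    def test_sample_sd_uses_n_minus_1(self):
        s = summarize_sizes(_table([2.0, 4.0, 6.0]))
        assert s.sd_um == pytest.approx(2.0)

    def test_histogram_sums_to_valid_n_and_ordering(self):
        rng = np.random.default_rng(1)
        d = rng.lognormal(np.log(3.7), 0.45, size=500)
        s = summarize_sizes(_table(list(d)))
        assert s.histogram_counts.sum() == s.valid_n == 500
        assert s.d10_um <= s.d50_um <= s.d90_um
        assert np.allclose(np.diff(s.histogram_edges_um), 0.5)

    def test_excluded_rows_ignored(self):
        t = _table([2.0, 4.0, 6.0])
        t.loc[2, "excluded_reason"] = "border"
        t.loc[2, "diameter_um"] = np.nan
        assert summarize_sizes(t).valid_n == 2

    def test_empty_table_raises(self):
        with pytest.raises(EmptyTableError):
            summarize_sizes(_table([]))


class TestOverlay:
    def test_empty_mask_reproduces_grayscale(self):
        px = np.random.default_rng(0).integers(0, 256, (32, 32)).astype(np.uint8)
        img = Micrograph(px, databar_height=0)
        out = render_overlay(img, np.zeros((32, 32), dtype=np.int32))
        assert out.shape == (32, 32, 3)
        assert np.array_equal(out[..., 0], px)
        assert np.array_equal(out[..., 1], px)

    def test_only_instance_pixels_tinted(self):
        px = np.full((32, 32), 100, dtype=np.uint8)
        m = np.zeros((32, 32), dtype=np.int32)
        m[4:10, 4:10] = 1
        out = render_overlay(Micrograph(px, databar_height=0), m)
        changed = np.any(out != 100, axis=2)
        assert np.array_equal(changed, m > 0)

    def test_palette_deterministic(self):
        px = np.zeros((16, 16), dtype=np.uint8)
        m = np.zeros((16, 16), dtype=np.int32)
        m[2:6, 2:6] = 1
        img = Micrograph(px, databar_height=0)
        assert np.array_equal(render_overlay(img, m), render_overlay(img, m))

    def test_shape_mismatch_rejected(self):
        img = Micrograph(np.zeros((16, 16), dtype=np.uint8), databar_height=0)
        with pytest.raises(ValueError):
            render_overlay(img, np.zeros((8, 8), dtype=np.int32))


class TestPipelineDeterminism:
    def test_bit_identical_particle_tables(self):
        p = MicrographSimParams(n_particles=25, image_width=400,
                                image_height=400, seed=6)
        img, _ = simulate_micrograph(p)
        t1, s1, m1 = imaging.size_micrograph(img)
        t2, s2, m2 = imaging.size_micrograph(img)
        assert np.array_equal(m1, m2)
        pd.testing.assert_frame_equal(
            t1.drop(columns="contour"), t2.drop(columns="contour")
        )
        assert s1.to_dict() == s2.to_dict()
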