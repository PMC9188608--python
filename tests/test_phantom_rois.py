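import math

import numpy as np
import pytest
from scipy import stats as sps

from microct_qc.errors import GeometryError, ValidationError
from microct_qc.phantom_rois import (
    CircularRoi,
    RoiMap,
    default_low_contrast_layout,
    extract_roi_stats,
    low_contrast_roi_map,
    radius_for_area_fraction,
    roi_mask,
    uniformity_roi_map,
    water_roi_map,
)
from microct_qc.synthetic_phantoms import PhantomSpec, gen_phantom
from microct_qc.volumes_io import Volume


class TestRoiSizingRule:
    @pytest.mark.parametrize(
        "diameter, expected_roi_area, expected_base_area",
        [(32.0, 80.4, 804.0), (20.0, 31.4, 314.0)],
    )
    def test_ten_percent_rule_matches_protocol_areas(
        self, diameter, expected_roi_area, expected_base_area
    ):
        r = radius_for_area_fraction(diameter, 0.10)
        assert round(math.pi * r**2, 1) == expected_roi_area
        assert round(math.pi * (diameter / 2) ** 2) == expected_base_area

    def test_full_area_fraction_returns_phantom_radius(self):
        assert radius_for_area_fraction(18.0, 1.0) == pytest.approx(9.0)

    @pytest.mark.parametrize("diameter, fraction", [(-1, 0.1), (32, 0.0), (32, 1.5)])
    def test_invalid_inputs_rejected(self, diameter, fraction):
        with pytest.raises(ValidationError):
            radius_for_area_fraction(diameter, fraction)


class TestWaterMap:
    def test_five_slice_window_centered_on_requested_slice(self):
        volume = Volume(np.zeros((64, 400, 400)), spacing=(0.1, 0.1, 0.1))
        roi = water_roi_map(volume, center_slice=32)["water"]
        assert roi.slice_range == (30, 34)
        assert roi.n_slices == 5

    def test_window_that_exits_volume_is_rejected(self):
        volume = Volume(np.zeros((5, 400, 400)), spacing=(0.1, 0.1, 0.1))
        with pytest.raises(ValidationError, match="center"):
            water_roi_map(volume, center_slice=1)

    def test_roi_sits_inside_generated_water_cylinder(self):
        volume, truth = gen_phantom(PhantomSpec(kind="water", noise_sd=0.0,
                                                spacing=0.2))
        roi = water_roi_map(volume)["water"]
        cx, cy = roi.center_xy
        assert math.hypot(cx, cy) + roi.radius < truth.phantom_radius


class TestUniformityMap:
    def test_layout_has_five_equal_rois_at_60pct_radius(self):
        volume = Volume(np.zeros((7, 360, 360)), spacing=(0.1, 0.1, 0.1),
                        origin=(0, -17.95, -17.95))
        roi_map = uniformity_roi_map(volume)
        assert roi_map.names == ("a", "b", "c", "d", "e")
        areas = {round(r.area, 9) for r in roi_map}
        assert len(areas) == 1
        center = roi_map["a"].center_xy
        for name in "bcde":
            dx = roi_map[name].center_xy[0] - center[0]
            dy = roi_map[name].center_xy[1] - center[1]
            assert math.hypot(dx, dy) == pytest.approx(0.6 * 16.0)

    def test_peripheral_rois_escaping_phantom_rejected(self):
        volume = Volume(np.zeros((7, 360, 360)), spacing=(0.1, 0.1, 0.1),
                        origin=(0, -17.95, -17.95))
        with pytest.raises(GeometryError, match="peripheral"):
            uniformity_roi_map(volume, peripheral_fraction=0.95)

    def test_radial_gradient_moves_peripheral_means_outward(self):
        """On a brighter-periphery phantom the peripheral ROI means exceed
        the central one by the analytic disk-mean of the gradient field."""
        spec = PhantomSpec(kind="water", noise_sd=0.0, gradient=10.0,
                           spacing=0.2)
        volume, _ = gen_phantom(spec)
        roi_map = uniformity_roi_map(volume)
        central = np.mean(extract_roi_stats(volume, roi_map["a"]).per_slice_mean)
        peripherals = [
            np.mean(extract_roi_stats(volume, roi_map[n]).per_slice_mean)
            for n in "bcde"
        ]
        # analytic disk means of |r| over central and offset disks
        r0 = radius_for_area_fraction(32.0, 0.1)
        d = 0.6 * 16.0
        grid = np.linspace(-r0, r0, 1201)
        X, Y = np.meshgrid(grid, grid)
        disk = X**2 + Y**2 <= r0**2
        central_r = np.hypot(X[disk], Y[disk]).mean()
        peri_r = np.hypot(X[disk] + d, Y[disk]).mean()
        expected_diff = 10.0 * (peri_r - central_r)
        measured_diff = np.mean(peripherals) - central
        assert measured_diff == pytest.approx(expected_diff, rel=0.05)
        assert all(p > central for p in peripherals)


class TestLowContrastMap:
    def test_map_has_eleven_named_rois_with_proportional_diameters(self):
        volume = Volume(np.zeros((100, 300, 300)), spacing=(0.1, 0.1, 0.1),
                        origin=(0, -14.95, -14.95))
        roi_map = low_contrast_roi_map(volume)
        assert len(roi_map.rois) == 11
        assert {"background", "air"} <= set(roi_map.names)
        for level in (-9, -6, -3):
            radii = [
                roi_map[f"insert_{level:+d}pct_{d}mm"].radius for d in (1, 2, 3)
            ]
            assert radii[1] / radii[0] == pytest.approx(2.0)
            assert radii[2] / radii[0] == pytest.approx(3.0)
        for roi in roi_map:
            assert roi.n_slices == 100

    def test_too_few_slices_rejected(self):
        volume = Volume(np.zeros((50, 300, 300)), spacing=(0.1, 0.1, 0.1),
                        origin=(0, -14.95, -14.95))
        with pytest.raises(ValidationError, match="100"):
            low_contrast_roi_map(volume)

    def test_overlapping_inserts_rejected(self):
        volume = Volume(np.zeros((100, 300, 300)), spacing=(0.1, 0.1, 0.1),
                        origin=(0, -14.95, -14.95))
        layout = default_low_contrast_layout(ring_radius=0.8)
        with pytest.raises(GeometryError, match="overlap"):
            low_contrast_roi_map(volume, layout=layout)

    def test_insert_means_match_generator_truth_at_zero_noise(self):
        spec = PhantomSpec(kind="low_contrast", noise_sd=0.0, spacing=0.1)
        volume, truth = gen_phantom(spec)
        roi_map = low_contrast_roi_map(volume, layout=truth.layout,
                                       start_slice=2)
        for site in truth.layout.inserts:
            stats = extract_roi_stats(volume, roi_map[site.name])
            assert np.mean(stats.per_slice_mean) == pytest.approx(
                truth.nominal[site.name], abs=1.0
            )


class TestRoiStats:
    def test_constant_volume_gives_constant_means_zero_sd(self, constant_volume):
        roi = CircularRoi("c", constant_volume.center_xy, 5.0, (0, 4))
        stats = extract_roi_stats(constant_volume, roi)
        assert stats.per_slice_mean == (2000.0,) * 5
        assert stats.per_slice_sd == (0.0,) * 5

    def test_hand_computed_three_by_three_patch(self):
        """A 3×3 patch holding 1..9: mean 5, sample SD sqrt(7.5)."""
        grid = np.zeros((1, 5, 5))
        grid[0, 1:4, 1:4] = np.arange(1, 10).reshape(3, 3)
        volume = Volume(grid, spacing=(1.0, 1.0, 1.0))
        roi = CircularRoi("patch", (2.0, 2.0), 1.5, (0, 0))
        stats = extract_roi_stats(volume, roi)
        assert roi_mask(volume, roi).sum() == 9
        assert stats.per_slice_mean[0] == pytest.approx(5.0)
        assert stats.per_slice_sd[0] == pytest.approx(math.sqrt(7.5))

    def test_gaussian_noise_sd_recovered_within_sampling_error(self, rng):
        sigma = 124.0
        volume = Volume(
            rng.normal(2000.0, sigma, size=(5, 160, 160)),
            spacing=(0.1, 0.1, 0.1),
            origin=(0, -7.95, -7.95),
        )
        roi = CircularRoi("big", (0.0, 0.0), 6.0, (0, 4))
        stats = extract_roi_stats(volume, roi)
        n = int(roi_mask(volume, roi).sum())
        assert n >= 10_000
        pooled = np.mean(stats.per_slice_sd)
        # 99% band of the mean of 5 slice SDs, from chi-square moments
        c4 = math.sqrt(2 / (n - 1)) * math.exp(
            math.lgamma(n / 2) - math.lgamma((n - 1) / 2)
        )
        se = sigma * math.sqrt((1 - c4**2) / 5)
        assert abs(pooled - sigma * c4) < 2.576 * se + 0.05 * sigma

    def test_sub_voxel_roi_is_rejected(self, constant_volume):
        roi = CircularRoi("tiny", (0.12, 0.12), 0.05, (0, 0))
        with pytest.raises(ValidationError, match="no voxel"):
            extract_roi_stats(constant_volume, roi)

    def test_area_and_voxel_count_agree_within_perimeter_band(self):
        volume = Volume(np.zeros((1, 400, 400)), spacing=(0.1, 0.1, 0.1),
                        origin=(0, -19.95, -19.95))
        for radius in (1.0, 3.3, 5.06, 9.0):
            roi = CircularRoi("r", (0.0, 0.0), radius, (0, 0))
            count_area = roi_mask(volume, roi).sum() * 0.1 * 0.1
            band = 2 * math.pi * radius * 0.1 + 4 * 0.01
            assert abs(count_area - roi.area) <= band

    def test_maps_are_pure_functions_of_geometry(self):
        volume = Volume(np.zeros((7, 360, 360)), spacing=(0.1, 0.1, 0.1),
                        origin=(0, -17.95, -17.95))
        assert uniformity_roi_map(volume) == uniformity_roi_map(volume)


def test_roi_map_json_round_trip(tmp_path):
    volume = Volume(np.zeros((7, 360, 360)), spacing=(0.1, 0.1, 0.1),
                    origin=(0, -17.95, -17.95))
    roi_map = uniformity_roi_map(volume)
    path = tmp_path / "map.json"
    roi_map.to_json(path)
    assert RoiMap.from_json(path) == roi_map


def test_duplicate_roi_names_rejected():
    roi = CircularRoi("x", (0, 0), 1.0, (0, 0))
    with pytest.raises(ValidationError, match="duplicate"):
        RoiMap(phantom_kind="water", rois=(roi, roi))
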