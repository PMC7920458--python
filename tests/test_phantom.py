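"""Phantom rendering, system blur, bias field and noise-model tests."""

import math

import numpy as np
import pytest

from tvphantom import (
    AcquisitionProfile,
    ConfigurationError,
    Image,
    NoiseSpec,
    PhantomSpec,
    add_gaussian_noise,
    apply_bias_field,
    apply_system_blur,
    bias_field,
    default_profiles,
    render_phantom,
    rod_layout,
)
from tvphantom.phantom import FWHM_PER_SIGMA


class TestPhantomSpec:
    def test_defaults_are_valid(self):
        spec = PhantomSpec()
        assert spec.cylinder_radius_mm < spec.grid_size * spec.pixel_mm / 2

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cylinder_radius_mm": 300.0},  # does not fit in the grid
            {"rod_sectors": ((5.0, 2.0), (5.0, 2.0))},  # duplicate diameters
            {"rod_sectors": ((-1.0, 2.0),)},  # non-positive diameter
            {"activity_in": 0.5, "activity_out": 0.5},  # no contrast
            {"activity_out": -0.1},  # negative background
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            PhantomSpec(**kwargs)

    def test_shipped_profiles_order_uniformity(self):
        caipi, grappa = default_profiles()
        assert caipi.bias_amplitude < grappa.bias_amplitude


class TestRodLayout:
    def test_all_rods_inside_cylinder(self):
        spec = PhantomSpec()
        for sector in rod_layout(spec):
            r = sector.rod_diameter_mm / 2
            for (x, y) in sector.centers_mm:
                assert math.hypot(x, y) + r <= spec.cylinder_radius_mm

    def test_rods_outside_clear_hub(self):
        spec = PhantomSpec()
        for sector in rod_layout(spec):
            r = sector.rod_diameter_mm / 2
            for (x, y) in sector.centers_mm:
                assert math.hypot(x, y) - r >= spec.center_clear_radius_mm

    def test_smaller_rods_are_more_numerous(self):
        counts = [s.n_rods for s in rod_layout(PhantomSpec())]
        assert counts == sorted(counts, reverse=True)

    def test_oversized_rod_sector_raises_naming_sector(self):
        spec = PhantomSpec.__new__(PhantomSpec)  # bypass to craft invalid geometry
        object.__setattr__(spec, "grid_size", 64)
        object.__setattr__(spec, "pixel_mm", 2.0)
        object.__setattr__(spec, "cylinder_radius_mm", 40.0)
        object.__setattr__(spec, "rod_sectors", ((90.0, 2.0),))
        object.__setattr__(spec, "activity_in", 1.0)
        object.__setattr__(spec, "activity_out", 0.0)
        object.__setattr__(spec, "rods_cold", True)
        object.__setattr__(spec, "center_clear_radius_mm", 20.0)
        with pytest.raises(ConfigurationError, match="sector 0"):
            rod_layout(spec)


class TestRenderPhantom:
    def test_no_rods_gives_uniform_disk(self):
        spec = PhantomSpec(grid_size=64, pixel_mm=4.0, rod_sectors=())
        img = render_phantom(spec)
        # strictly interior pixels (one pixel inside the rim) are exactly hot
        pos = (np.arange(64) - 31.5) * 4.0
        rr = np.hypot(pos[:, None], pos[None, :])
        interior = rr < spec.cylinder_radius_mm - 2 * spec.pixel_mm
        assert np.all(img.values[interior] == spec.activity_in)
        exterior = rr > spec.cylinder_radius_mm + 2 * spec.pixel_mm
        assert np.all(img.values[exterior] == spec.activity_out)

    def test_degenerate_contrast_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomSpec(activity_in=1.0, activity_out=1.0)

    def test_rendering_is_deterministic(self, small_phantom_spec):
        a = render_phantom(small_phantom_spec)
        b = render_phantom(small_phantom_spec)
        np.testing.assert_array_equal(a.values, b.values)

    def test_hot_area_matches_analytic_disk_minus_rods(self):
        """Pixel-counted hot area agrees with pi*R^2 - sum(pi*r^2) within 1%."""
        spec = PhantomSpec()
        img = render_phantom(spec)
        hot_pixels = int((img.values > 0.5).sum())
        hot_area = hot_pixels * spec.pixel_mm**2
        rod_area = sum(
            s.n_rods * math.pi * (s.rod_diameter_mm / 2) ** 2
            for s in rod_layout(spec)
        )
        analytic = math.pi * spec.cylinder_radius_mm**2 - rod_area
        assert abs(hot_area - analytic) / analytic < 0.01

    def test_values_bounded_by_activities(self, small_phantom_spec):
        img = render_phantom(small_phantom_spec)
        assert img.values.min() >= small_phantom_spec.activity_out
        assert img.values.max() <= small_phantom_spec.activity_in


class TestSystemBlur:
    def test_zero_fwhm_is_identity(self, small_phantom_spec):
        img = render_phantom(small_phantom_spec)
        out = apply_system_blur(img, 0.0)
        np.testing.assert_array_equal(out.values, img.values)

    def test_constant_image_preserved(self):
        img = Image(np.full((32, 32), 0.7), pixel_mm=2.0)
        out = apply_system_blur(img, 6.0)
        np.testing.assert_allclose(out.values, 0.7, rtol=1e-12)

    def test_impulse_peak_matches_gaussian_normalization(self):
        """Blurred unit impulse peaks at the 2-D Gaussian height 1/(2 pi sigma_px^2)."""
        values = np.zeros((129, 129))
        values[64, 64] = 1.0
        img = Image(values, pixel_mm=2.0)
        fwhm = 8.0
        out = apply_system_blur(img, fwhm)
        sigma_px = fwhm / FWHM_PER_SIGMA / img.pixel_mm
        expected_peak = 1.0 / (2 * math.pi * sigma_px**2)
        assert out.values[64, 64] == pytest.approx(expected_peak, rel=0.02)

    def test_interior_intensity_conserved(self, small_phantom_spec):
        img = render_phantom(small_phantom_spec)
        out = apply_system_blur(img, 4.0)
        assert out.values.sum() == pytest.approx(img.values.sum(), rel=1e-3)

    def test_blur_reduces_rod_contrast(self):
        spec = PhantomSpec()
        img = render_phantom(spec)
        out = apply_system_blur(img, 6.0)
        masks = _rod_center_indices(spec)
        for rows, cols in masks.values():
            before = spec.activity_in - img.values[rows, cols].mean()
            after = spec.activity_in - out.values[rows, cols].mean()
            assert after < before

    def test_partial_volume_monotonic_in_rod_diameter(self):
        """Smaller rods lose more apparent (cold) contrast under a fixed PSF."""
        spec = PhantomSpec()
        blurred = apply_system_blur(render_phantom(spec), 6.0)
        contrast_by_diameter = {}
        for diameter, (rows, cols) in _rod_center_indices(spec).items():
            # cold-rod contrast: how far the rod centre drops below the hot level
            contrast_by_diameter[diameter] = (
                spec.activity_in - blurred.values[rows, cols].mean()
            )
        diameters = sorted(contrast_by_diameter)
        contrasts = [contrast_by_diameter[d] for d in diameters]
        assert contrasts == sorted(contrasts)


def _rod_center_indices(spec):
    """Nearest-pixel indices of every rod centre, keyed by rod diameter."""
    out = {}
    c = (spec.grid_size - 1) / 2.0
    for sector in rod_layout(spec):
        rows = [int(round(y / spec.pixel_mm + c)) for _, y in sector.centers_mm]
        cols = [int(round(x / spec.pixel_mm + c)) for x, _ in sector.centers_mm]
        out[sector.rod_diameter_mm] = (np.array(rows), np.array(cols))
    return out


class TestBiasField:
    def test_zero_amplitude_is_identity(self):
        img = Image(np.linspace(0, 1, 32 * 32).reshape(32, 32))
        profile = AcquisitionProfile(name="flat", bias_amplitude=0.0)
        out = apply_bias_field(img, profile, seed=3)
        np.testing.assert_array_equal(out.values, img.values)

    def test_constant_input_bounded_by_amplitude(self):
        img = Image(np.full((64, 64), 0.8), pixel_mm=2.0)
        a = 0.08
        profile = AcquisitionProfile(name="p", bias_amplitude=a)
        out = apply_bias_field(img, profile, seed=5)
        assert out.values.min() >= 0.8 * (1 - a) - 1e-12
        assert out.values.max() <= 0.8 * (1 + a) + 1e-12

    def test_same_seed_bitwise_identical(self):
        img = Image(np.full((48, 48), 1.0))
        profile = AcquisitionProfile(name="p", bias_amplitude=0.05)
        a = apply_bias_field(img, profile, seed=9)
        b = apply_bias_field(img, profile, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_peak_relative_deviation_equals_amplitude(self):
        b = bias_field((128, 128), AcquisitionProfile("p", 0.08), 2.0, seed=2)
        assert np.abs(b).max() == pytest.approx(0.08, rel=1e-12)
        assert b.max() <= 0.0  # field models regional signal loss

    def test_amplitude_scales_the_same_shape(self):
        lo = bias_field((64, 64), AcquisitionProfile("a", 0.02), 2.0, seed=4)
        hi = bias_field((64, 64), AcquisitionProfile("b", 0.08), 2.0, seed=4)
        np.testing.assert_allclose(hi, 4.0 * lo, rtol=1e-12)


class TestGaussianNoise:
    def test_zero_variance_identity(self):
        img = Image(np.full((16, 16), 0.5))
        out = add_gaussian_noise(img, NoiseSpec(variance=0.0, seed=1))
        np.testing.assert_array_equal(out.values, img.values)

    def test_sample_variance_matches_spec(self):
        """Added-noise sample variance on 256^2 pixels is within 5% of 0.001."""
        img = Image(np.full((256, 256), 0.5))
        out = add_gaussian_noise(img, NoiseSpec(variance=0.001, seed=7))
        diff = out.values - img.values
        assert diff.var() == pytest.approx(0.001, rel=0.05)
        assert abs(diff.mean()) < 5 * math.sqrt(0.001 / 256**2) + 1e-4

    def test_seed_contract(self):
        img = Image(np.full((32, 32), 0.5))
        a = add_gaussian_noise(img, NoiseSpec(variance=0.001, seed=3))
        b = add_gaussian_noise(img, NoiseSpec(variance=0.001, seed=3))
        c = add_gaussian_noise(img, NoiseSpec(variance=0.001, seed=4))
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigurationError):
            NoiseSpec(variance=-0.001)

    def test_rescales_when_above_unit_range(self):
        img = Image(np.full((16, 16), 2.0))
        out = add_gaussian_noise(img, NoiseSpec(variance=0.0, seed=1))
        np.testing.assert_allclose(out.values, 1.0)
        assert "rescaled" in out.provenance

    def test_no_clipping_of_negative_excursions(self):
        img = Image(np.zeros((64, 64)) + 1e-6)
        out = add_gaussian_noise(img, NoiseSpec(variance=0.001, seed=5))
        assert out.values.min() < 0  # Gaussian tails kept, not clipped
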