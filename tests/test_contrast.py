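import numpy as np
import pytest

from sharkvis.contrast import (
    ThresholdModel,
    depth_detectability_profile,
    detectable,
    michelson_contrast,
    pigment_locus,
    quantum_catch,
    weber_contrast,
)
from sharkvis.light import LightField, downwelling, flat_surface, spacelight
from sharkvis.pigments import VisualPigmentTemplate, template_absorbance
from sharkvis.spectra import SpectralCurve, integrate

from oracles import brute_force_locus_optimum


def narrowband(center, height, width=1.0):
    return SpectralCurve(
        np.array([center - width, center, center + width]),
        np.array([0.0, height, 0.0]),
    )


class TestQuantumCatch:
    def test_flat_radiance_equals_template_area(self, template_484):
        level = 2.5
        flat = SpectralCurve.constant(level, template_484.wavelengths)
        q = quantum_catch(template_484, flat)
        assert q == pytest.approx(level * integrate(template_484), rel=1e-9)

    def test_monochromatic_at_peak_vs_half_sensitivity(self, template_484):
        q_peak = quantum_catch(template_484, narrowband(484.0, 1.0))
        # find a wavelength where the template is ~0.5
        lam_half = 450.0
        s_half = template_484(lam_half)
        q_half = quantum_catch(template_484, narrowband(lam_half, 1.0))
        assert q_half / q_peak == pytest.approx(s_half / template_484(484.0), rel=0.05)

    def test_disjoint_supports_zero_with_warning(self, template_484):
        uv = SpectralCurve(np.array([200.0, 250.0]), np.array([1.0, 1.0]))
        with pytest.warns(UserWarning, match="disjoint"):
            assert quantum_catch(template_484, uv) == 0.0

    def test_bilinearity(self, template_484):
        grid = template_484.wavelengths
        rng = np.random.default_rng(3)
        r1 = SpectralCurve(grid, rng.uniform(0, 1, grid.size))
        r2 = SpectralCurve(grid, rng.uniform(0, 1, grid.size))
        a, b = 1.7, 0.4
        lhs = quantum_catch(template_484, r1 * a + r2 * b)
        rhs = a * quantum_catch(template_484, r1) + b * quantum_catch(template_484, r2)
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestContrastMetrics:
    @pytest.mark.parametrize(
        "qt, qb, expected", [(1.0, 1.0, 0.0), (2.0, 1.0, 1.0), (0.0, 1.0, -1.0)]
    )
    def test_weber_values(self, qt, qb, expected):
        assert weber_contrast(qt, qb) == pytest.approx(expected)

    def test_weber_requires_positive_background(self):
        with pytest.raises(ValueError):
            weber_contrast(1.0, 0.0)

    def test_michelson_bounded(self):
        assert -1.0 <= michelson_contrast(0.3, 2.0) <= 1.0

    def test_detectable_rules(self):
        th = ThresholdModel(min_contrast=0.02, min_catch=100.0)
        assert detectable(0.5, 1e6, th)
        assert not detectable(0.5, 10.0, th)       # starlight-starved
        assert not detectable(0.001, 1e6, th)      # below contrast threshold


class TestPigmentLocus:
    def test_identical_target_background_flat_locus(self, blue_water):
        lf = LightField(flat_surface(), blue_water, 10.0)
        bg = spacelight(lf)
        locus = pigment_locus(bg, bg, np.arange(440.0, 521.0, 5.0))
        np.testing.assert_allclose(locus.contrast_by_lambda, 0.0, atol=1e-12)

    def test_gray_world_null(self, blue_water):
        """target = k * background => Weber contrast k-1 for every pigment."""
        lf = LightField(flat_surface(), blue_water, 20.0)
        bg = spacelight(lf)
        k = 2.5
        locus = pigment_locus(bg.scaled(k), bg, np.arange(420.0, 541.0, 10.0))
        np.testing.assert_allclose(locus.contrast_by_lambda, k - 1.0, rtol=1e-9)

    def test_gray_target_optimum_matches_background_peak(self, blue_water):
        lf = LightField(flat_surface(), blue_water, 30.0)
        bg = spacelight(lf)
        gray = downwelling(lf).scaled(0.3 / np.pi)
        locus = pigment_locus(gray, bg)
        assert abs(locus.optimum - bg.peak_wavelength) <= 10.0

    def test_optimum_equals_brute_force(self, blue_water):
        lf = LightField(flat_surface(), blue_water, 30.0)
        bg = spacelight(lf)
        grid = np.arange(430.0, 531.0, 1.0)
        # a structured (non-gray) target: fluorescent green bump over gray
        grid_c = bg.wavelengths
        bump = 0.4 * np.exp(-0.5 * ((grid_c - 530.0) / 15.0) ** 2)
        target = SpectralCurve(grid_c, bg.values * (0.5 + bump))
        locus = pigment_locus(target, bg, grid)
        assert locus.optimum == brute_force_locus_optimum(target, bg, grid)


class TestDepthProfile:
    def test_zero_contrast_for_identical_patches(self, patch_pair, blue_water):
        beige, _ = patch_pair
        prof = depth_detectability_profile(
            beige, beige, blue_water, [0.0], VisualPigmentTemplate(484.0)
        )
        assert len(prof) == 1
        assert prof[0].weber == pytest.approx(0.0, abs=1e-12)

    def test_detectable_at_30m(self, patch_pair, blue_water):
        beige, dark = patch_pair
        prof = depth_detectability_profile(
            beige, dark, blue_water, [30.0], VisualPigmentTemplate(484.0)
        )
        assert prof[0].detectable

    def test_fluorescence_strengthens_contrast(self, patch_pair, blue_water):
        """The central mechanism: at depth, fluorescing patches show larger
        |Weber contrast| than the same patches with fluorescence removed."""
        beige, dark = patch_pair
        pig = VisualPigmentTemplate(484.0)
        with_f = depth_detectability_profile(
            beige, dark, blue_water, [10.0, 20.0, 30.0], pig
        )
        without_f = depth_detectability_profile(
            beige.without_fluorescence(),
            dark.without_fluorescence(),
            blue_water,
            [10.0, 20.0, 30.0],
            pig,
        )
        for a, b in zip(with_f, without_f):
            assert abs(a.weber) > abs(b.weber)

    def test_depths_must_increase(self, patch_pair, blue_water):
        beige, dark = patch_pair
        with pytest.raises(ValueError):
            depth_detectability_profile(
                beige, dark, blue_water, [10.0, 5.0], VisualPigmentTemplate(484.0)
            )
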