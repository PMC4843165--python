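import numpy as np
import pytest

from sharkvis.colorimetry import (
    cie_1931_cmfs,
    monochromat_lightness,
    patch_contrast_ratio,
    render_patch_pair,
    spectrum_to_xyz,
)
from sharkvis.fluorescence import skin_radiance
from sharkvis.light import LightField, WaterType, flat_surface
from sharkvis.pigments import VisualPigmentTemplate
from sharkvis.spectra import SpectralCurve
from sharkvis.synth import gen_patch_pair


def white_light_field():
    clear = WaterType("clear", SpectralCurve.constant(0.0))
    return LightField(flat_surface(1.0), clear, 0.0)


def blue_470_field():
    grid = np.arange(300.0, 701.0, 1.0)
    clear = WaterType("clear", SpectralCurve.constant(0.0))
    mono = SpectralCurve(grid, np.where(np.abs(grid - 470.0) <= 5, 1.0, 0.0))
    return LightField(mono, clear, 0.0)


class TestSpectrumToXYZ:
    def test_zero_spectrum_zero_color(self):
        c = spectrum_to_xyz(SpectralCurve.constant(0.0))
        assert (c.X, c.Y, c.Z) == (0.0, 0.0, 0.0)
        assert c.rgb == (0.0, 0.0, 0.0)

    def test_equal_energy_chromaticity(self):
        grid = np.arange(360.0, 781.0, 1.0)
        c = spectrum_to_xyz(SpectralCurve.constant(1.0, grid))
        x, y = c.chromaticity
        assert x == pytest.approx(1.0 / 3.0, abs=0.01)
        assert y == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_linearity_in_radiance(self):
        grid = np.arange(380.0, 701.0, 1.0)
        rng = np.random.default_rng(5)
        r = SpectralCurve(grid, rng.uniform(0, 1, grid.size))
        c1 = spectrum_to_xyz(r)
        c2 = spectrum_to_xyz(r * 2.0)
        assert c2.X == pytest.approx(2 * c1.X, rel=1e-12)
        assert c2.Y == pytest.approx(2 * c1.Y, rel=1e-12)
        assert c2.Z == pytest.approx(2 * c1.Z, rel=1e-12)

    def test_additivity(self):
        grid = np.arange(380.0, 701.0, 1.0)
        rng = np.random.default_rng(6)
        r1 = SpectralCurve(grid, rng.uniform(0, 1, grid.size))
        r2 = SpectralCurve(grid, rng.uniform(0, 1, grid.size))
        c = spectrum_to_xyz(r1 + r2)
        ca, cb = spectrum_to_xyz(r1), spectrum_to_xyz(r2)
        assert c.X == pytest.approx(ca.X + cb.X, rel=1e-12)

    def test_cmfs_equal_integrals(self):
        x, y, z = cie_1931_cmfs()
        ints = [np.trapezoid(c.values, c.wavelengths) for c in (x, y, z)]
        assert ints[0] == pytest.approx(ints[1], rel=1e-9)
        assert ints[2] == pytest.approx(ints[1], rel=1e-9)


class TestMonochromat:
    def test_zero_radiance_zero_lightness(self):
        pig = VisualPigmentTemplate(484.0)
        assert monochromat_lightness(SpectralCurve.constant(0.0), pig) == 0.0

    def test_metamerism_equal_catch_equal_lightness(self):
        """Spectra of different hue but equal catch are indistinguishable."""
        pig = VisualPigmentTemplate(484.0)
        blue = SpectralCurve(
            np.array([449.0, 450.0, 451.0]), np.array([0.0, 1.0, 0.0])
        )
        green = SpectralCurve(
            np.array([529.0, 530.0, 531.0]), np.array([0.0, 1.0, 0.0])
        )
        lb = monochromat_lightness(blue, pig)
        lg = monochromat_lightness(green, pig)
        scale = lb / lg
        assert monochromat_lightness(green * scale, pig) == pytest.approx(
            lb, rel=1e-9
        )

    def test_lightness_ordering_scale_invariant(self):
        pig = VisualPigmentTemplate(484.0)
        beige, dark = gen_patch_pair("C_ventriosum")
        lf = white_light_field()
        lb = monochromat_lightness(skin_radiance(beige, lf), pig)
        ld = monochromat_lightness(skin_radiance(dark, lf), pig)
        assert lb > ld
        assert 10 * lb > 10 * ld  # global scaling preserves order

    def test_beige_lighter_than_dark_under_white_light(self):
        beige, dark = gen_patch_pair("C_ventriosum")
        lf = white_light_field()
        pig = VisualPigmentTemplate(484.0)
        assert monochromat_lightness(
            skin_radiance(beige, lf), pig
        ) > monochromat_lightness(skin_radiance(dark, lf), pig)


class TestPatchContrastRatio:
    def test_identical_patches_ratio_one(self, template_484):
        r = SpectralCurve.constant(1.0)
        assert patch_contrast_ratio(r, r, template_484) == pytest.approx(1.0)

    def test_half_catch_ratio_two(self, template_484):
        r = SpectralCurve.constant(1.0)
        assert patch_contrast_ratio(r, r * 0.5, template_484) == pytest.approx(2.0)

    def test_zero_dark_patch_flagged_infinite(self, template_484):
        r = SpectralCurve.constant(1.0)
        with pytest.warns(UserWarning, match="infinite"):
            assert patch_contrast_ratio(
                r, SpectralCurve.constant(0.0), template_484
            ) == float("inf")

    def test_fluorescence_increases_ratio_under_470nm_light(self):
        """Patch contrast for the monochromat rises when fluorescence is on,
        under narrowband blue excitation."""
        beige, dark = gen_patch_pair("C_ventriosum")
        pig = VisualPigmentTemplate(484.0)
        lf = blue_470_field()
        with_f = patch_contrast_ratio(
            skin_radiance(beige, lf), skin_radiance(dark, lf), pig
        )
        without_f = patch_contrast_ratio(
            skin_radiance(beige.without_fluorescence(), lf),
            skin_radiance(dark.without_fluorescence(), lf),
            pig,
        )
        assert with_f > without_f


class TestRenderPatchPair:
    def test_white_normalization_exact(self, template_484):
        beige, dark = gen_patch_pair("C_ventriosum")
        lf = white_light_field()
        brgb, drgb, ratio = render_patch_pair(
            skin_radiance(beige, lf),
            skin_radiance(dark, lf),
            VisualPigmentTemplate(484.0),
        )
        assert brgb == (255.0, 255.0, 255.0)
        assert ratio > 1.0
        assert all(0.0 <= v < 255.0 for v in drgb)

    def test_human_observer_white_normalized(self):
        beige, dark = gen_patch_pair("C_ventriosum")
        lf = white_light_field()
        brgb, drgb, ratio = render_patch_pair(
            skin_radiance(beige, lf), skin_radiance(dark, lf), "human"
        )
        assert all(v == pytest.approx(255.0, abs=1e-6) for v in brgb)
        assert ratio > 1.0
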