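import numpy as np
import pytest

from sharkvis.fluorescence import EEM, SkinPatch, emission_under_excitation, skin_radiance
from sharkvis.light import LightField, water_type
from sharkvis.spectra import SpectralCurve, integrate
from sharkvis.synth import gen_species_eem


def delta_excitation(center, height=1.0):
    return SpectralCurve(
        np.array([center - 1.0, center, center + 1.0]),
        np.array([0.0, height, 0.0]),
    )


def small_eem(qe=0.5):
    ex = np.array([350.0, 400.0, 450.0])
    em = np.arange(460.0, 601.0, 10.0)
    eff = np.ones((3, em.size)) * qe / (em[-1] - em[0])
    return EEM(ex, em, eff)


class TestEEMValidation:
    def test_anti_stokes_entries_zeroed_with_warning(self):
        ex = np.array([400.0, 500.0])
        em = np.array([450.0, 550.0])
        eff = np.full((2, 2), 1e-3)
        with pytest.warns(UserWarning, match="anti-Stokes"):
            eem = EEM(ex, em, eff)
        assert eem.efficiency[1, 0] == 0.0  # 450 em under 500 ex
        assert eem.efficiency[0, 1] == pytest.approx(1e-3)

    def test_quantum_efficiency_bound_enforced(self):
        ex = np.array([350.0, 400.0])
        em = np.arange(450.0, 551.0, 10.0)
        with pytest.raises(ValueError, match="quantum-efficiency"):
            EEM(ex, em, np.full((2, em.size), 1.0))

    def test_csv_round_trip(self, tmp_path):
        eem = small_eem()
        path = tmp_path / "eem.csv"
        eem.to_csv(path)
        back = EEM.from_csv(path)
        np.testing.assert_allclose(back.excitation_grid, eem.excitation_grid)
        np.testing.assert_allclose(back.efficiency, eem.efficiency, rtol=1e-6)


class TestEmission:
    def test_zero_excitation_gives_zero(self):
        eem = small_eem()
        em = emission_under_excitation(eem, SpectralCurve.constant(0.0))
        assert em.max_value == 0.0

    def test_delta_excitation_selects_row(self):
        eem = small_eem()
        # narrow triangle at one excitation line: emission proportional to
        # that EEM row (here all rows are equal and flat)
        em = emission_under_excitation(eem, delta_excitation(400.0))
        assert em.values.min() > 0
        np.testing.assert_allclose(em.values, em.values[0], rtol=1e-9)

    def test_disjoint_grids_rejected(self):
        eem = small_eem()
        far_uv = SpectralCurve(np.array([250.0, 300.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="disjoint"):
            emission_under_excitation(eem, far_uv)

    def test_linearity_in_excitation(self):
        eem = gen_species_eem("C_ventriosum")
        exc = delta_excitation(400.0)
        em1 = emission_under_excitation(eem, exc)
        em2 = emission_under_excitation(eem, exc * 2.0)
        np.testing.assert_allclose(em2.values, 2.0 * em1.values, rtol=1e-12)

    def test_photon_bookkeeping(self):
        """Emitted photons never exceed incident excitation photons."""
        for eem in (small_eem(), gen_species_eem("C_ventriosum")):
            exc = SpectralCurve.constant(
                1.0, np.arange(eem.excitation_grid[0], eem.excitation_grid[-1] + 1)
            )
            em = emission_under_excitation(eem, exc)
            incident = integrate(
                SpectralCurve(eem.excitation_grid, exc(eem.excitation_grid))
            )
            assert integrate(em) <= incident + 1e-9

    def test_stokes_shift_of_emission(self):
        eem = gen_species_eem("C_ventriosum")
        for ex in (355.0, 390.0, 470.0):
            em = emission_under_excitation(eem, delta_excitation(ex))
            assert em.peak_wavelength > ex


class TestSkinRadiance:
    def test_zero_eem_gives_pure_reflection(self, blue_water):
        grid = np.arange(300.0, 701.0, 1.0)
        patch = SkinPatch(
            "test",
            SpectralCurve.constant(0.5, grid),
            EEM.zero(np.array([350.0, 450.0]), np.array([500.0, 600.0])),
        )
        lf = LightField(SpectralCurve.constant(1.0, grid), blue_water, 10.0)
        rad = skin_radiance(patch, lf)
        from sharkvis.light import downwelling

        np.testing.assert_allclose(
            rad.values, 0.5 * downwelling(lf).values / np.pi, rtol=1e-12
        )

    def test_zero_reflectance_monochromatic_field_gives_pure_fluorescence(self):
        grid = np.arange(300.0, 701.0, 1.0)
        eem = gen_species_eem("C_ventriosum")
        patch = SkinPatch("fluor-only", SpectralCurve.constant(0.0, grid), eem)
        # monochromatic 470 nm ambient field in transparent water
        from sharkvis.light import WaterType

        clear = WaterType("clear", SpectralCurve.constant(0.0))
        mono = SpectralCurve(grid, np.where(np.abs(grid - 470.0) <= 2, 1.0, 0.0))
        rad = skin_radiance(patch, LightField(mono, clear, 5.0))
        assert rad.max_value > 0
        assert 525.0 <= rad.peak_wavelength <= 535.0

    def test_fluorescence_adds_green_radiance(self, patch_pair, blue_water):
        beige, _ = patch_pair
        lf = LightField(SpectralCurve.constant(1.0), blue_water, 30.0)
        with_f = skin_radiance(beige, lf)
        without_f = skin_radiance(beige.without_fluorescence(), lf)
        assert with_f(530.0) > without_f(530.0)
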