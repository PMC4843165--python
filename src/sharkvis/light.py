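"""Depth-resolved underwater light fields.

Downwelling irradiance is modelled with the standard diffuse-attenuation
law, E_d(lambda, z) = E_d(lambda, 0) * exp(-Kd(lambda) * z): each wavelength
decays exponentially with depth at its own rate, so the spectrum both dims
and narrows toward the attenuation minimum as depth increases.  Horizontal
background spacelight is taken proportional to the downwelling irradiance
(configurable constant); the contrast analysis downstream only uses its
spectral shape.

Two water classes are packaged, tabulated at 5 nm and interpolated:

* ``blue`` — oligotrophic oceanic water: pure-water absorption plus a weak
  CDOM exponential; attenuation minimum near 450-480 nm.
* ``blue-green`` — more productive water: stronger CDOM plus chlorophyll
  absorption at 440 nm, an accessory-pigment band near 625 nm and a minor
  675 nm band, which together push the transmission window to ~500-530 nm
  and narrow the depth spectrum sharply.

The pure-water backbone is a smoothed representative absorption table (m^-1,
10 nm steps); any other water can be supplied as a two-column Kd CSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import CANONICAL_GRID, SpectralCurve, resample

__all__ = [
    "WaterType",
    "LightField",
    "water_type",
    "downwelling",
    "spacelight",
    "flat_surface",
    "daylight_surface",
]

# Smoothed pure-water diffuse attenuation backbone, m^-1 (300-700 nm, 10 nm).
_KW_WAVELENGTHS = np.arange(300.0, 701.0, 10.0)
_KW_VALUES = np.array([
    0.150, 0.120, 0.095, 0.077, 0.063,   # 300-340
    0.050, 0.041, 0.033, 0.027, 0.022,   # 350-390
    0.018, 0.015, 0.013, 0.0117, 0.0106, # 400-440
    0.0097, 0.0096, 0.0100, 0.0114, 0.0140, # 450-490
    0.0230, 0.0340, 0.0450, 0.0500, 0.0550, # 500-540
    0.0630, 0.0700, 0.0750, 0.0850, 0.130,  # 550-590
    0.220, 0.250, 0.280, 0.300, 0.320,   # 600-640
    0.350, 0.400, 0.430, 0.450, 0.500,   # 650-690
    0.650,                                # 700
])

#: 5 nm tabulation grid for the packaged water types.
_KD_GRID = np.arange(300.0, 700.0 + 5.0, 5.0)


def _kd_blue(lam: np.ndarray) -> np.ndarray:
    kw = np.interp(lam, _KW_WAVELENGTHS, _KW_VALUES)
    cdom = 0.45 * np.exp(-(lam - 300.0) / 35.0)
    return kw + cdom


def _kd_blue_green(lam: np.ndarray) -> np.ndarray:
    kw = np.interp(lam, _KW_WAVELENGTHS, _KW_VALUES)
    cdom = 2.5 * np.exp(-(lam - 300.0) / 40.0)
    chl_blue = 0.25 * np.exp(-(((lam - 440.0) / 45.0) ** 2))
    # accessory-pigment absorption (chlorophyll shoulder / phycobilins)
    # steepening the long-wave flank of the transmission window
    accessory = 0.45 * np.exp(-(((lam - 625.0) / 70.0) ** 2))
    chl_red = 0.05 * np.exp(-(((lam - 675.0) / 21.0) ** 2))
    return kw + cdom + chl_blue + accessory + chl_red


_WATER_BUILDERS = {"blue": _kd_blue, "blue-green": _kd_blue_green}


@dataclass(frozen=True)
class WaterType:
    """A named water optical class: diffuse attenuation Kd(lambda), m^-1."""

    name: str
    kd: SpectralCurve


def water_type(name: str) -> WaterType:
    """Return a packaged water class ('blue' or 'blue-green')."""
    key = name.lower().replace("_", "-").replace("bluegreen", "blue-green")
    if key not in _WATER_BUILDERS:
        raise ValueError(
            f"unknown water type {name!r}; packaged types: "
            f"{sorted(_WATER_BUILDERS)} (or load a Kd CSV)"
        )
    return WaterType(key, SpectralCurve(_KD_GRID, _WATER_BUILDERS[key](_KD_GRID)))


def water_type_from_csv(name: str, path) -> WaterType:
    return WaterType(name, SpectralCurve.from_csv(path))


def flat_surface(
    amplitude: float = 1e18, grid: np.ndarray = CANONICAL_GRID
) -> SpectralCurve:
    """Spectrally flat quantal surface irradiance (photons m^-2 s^-1 nm^-1).

    The default amplitude is a nominal full-daylight order of magnitude; all
    contrast results downstream are ratios, so the absolute level only
    matters against the photon-catch detection threshold.
    """
    return SpectralCurve.constant(amplitude, grid)


def daylight_surface(
    amplitude: float = 1e18, grid: np.ndarray = CANONICAL_GRID
) -> SpectralCurve:
    """Smooth daylight-shaped quantal spectrum (6500 K Planck shape in
    photon units, peak-normalized then scaled by ``amplitude``)."""
    grid = np.asarray(grid, dtype=float)
    lam_m = grid * 1e-9
    h, c, kb, T = 6.62607e-34, 2.99792e8, 1.380649e-23, 6500.0
    # photon spectral radiance shape ~ lam^-4 / (exp(hc/lam k T) - 1)
    shape = lam_m**-4 / np.expm1(h * c / (lam_m * kb * T))
    shape /= shape.max()
    return SpectralCurve(grid, amplitude * shape)


@dataclass(frozen=True)
class LightField:
    """Surface spectrum + water class + depth (m)."""

    surface: SpectralCurve
    water: WaterType
    depth: float

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"depth must be nonnegative, got {self.depth}")


def downwelling(lf: LightField) -> SpectralCurve:
    """Downwelling irradiance at depth: E_d(lambda,0) * exp(-Kd * z)."""
    grid = lf.surface.wavelengths
    kd = resample(lf.water.kd, grid)
    return SpectralCurve(grid, lf.surface.values * np.exp(-kd.values * lf.depth))


def spacelight(lf: LightField, k: float = 0.01) -> SpectralCurve:
    """Horizontal background radiance, modelled as k * downwelling.

    A proportional spacelight preserves the downwelling spectral shape,
    which is all the luminosity-contrast analysis needs; k defaults to 0.01.
    """
    if k < 0:
        raise ValueError("spacelight proportionality must be nonnegative")
    return downwelling(lf).scaled(k)
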