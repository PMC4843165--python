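"""Trichromatic (CIE 1931) and monochromatic rendering of spectra.

Spectra are rendered two ways:

* to sRGB via the CIE 1931 2-degree standard observer (XYZ tristimulus
  integration, linear sRGB matrix for D65, standard piecewise transfer
  curve, clipped to [0, 255] with an out-of-gamut flag) — the "human view";
* to a single lightness value proportional to the quantum catch of a visual
  pigment template — the "monochromat view" of a single-pigment shark eye,
  for which any two spectra with equal catch are indistinguishable.

The colour-matching functions use the Wyman, Sloan & Shirley (2013)
piecewise-Gaussian analytic fits to the CIE 1931 2-degree observer, rescaled
so the three functions share equal integrals on the working grid (the CIE
equal-energy normalization convention), so an equal-energy spectrum maps to
chromaticity (1/3, 1/3) by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .contrast import quantum_catch
from .pigments import VisualPigmentTemplate, template_absorbance
from .spectra import SpectralCurve

__all__ = [
    "TristimulusColor",
    "cie_1931_cmfs",
    "spectrum_to_xyz",
    "xyz_to_srgb",
    "monochromat_lightness",
    "patch_contrast_ratio",
    "render_patch_pair",
]


def _pgauss(lam, mu, s1, s2):
    """Piecewise Gaussian: width s1 below the mode, s2 above."""
    s = np.where(lam < mu, s1, s2)
    return np.exp(-0.5 * ((lam - mu) / s) ** 2)


def _xbar(lam):
    return (1.056 * _pgauss(lam, 599.8, 37.9, 31.0)
            + 0.362 * _pgauss(lam, 442.0, 16.0, 26.7)
            - 0.065 * _pgauss(lam, 501.1, 20.4, 26.2))


def _ybar(lam):
    return (0.821 * _pgauss(lam, 568.8, 46.9, 40.5)
            + 0.286 * _pgauss(lam, 530.9, 16.3, 31.1))


def _zbar(lam):
    return (1.217 * _pgauss(lam, 437.0, 11.8, 36.0)
            + 0.681 * _pgauss(lam, 459.0, 26.0, 13.8))


#: Default colorimetric integration grid (the observer is negligible
#: outside 360-780 nm).
CMF_GRID = np.arange(360.0, 781.0, 1.0)


def cie_1931_cmfs(grid: np.ndarray = CMF_GRID):
    """(xbar, ybar, zbar) on ``grid``, equal-integral normalized."""
    grid = np.asarray(grid, dtype=float)
    x = np.clip(_xbar(grid), 0.0, None)
    y = np.clip(_ybar(grid), 0.0, None)
    z = np.clip(_zbar(grid), 0.0, None)
    ints = [np.trapezoid(c, grid) for c in (x, y, z)]
    ref = ints[1]
    x *= ref / ints[0]
    z *= ref / ints[2]
    return (SpectralCurve(grid, x), SpectralCurve(grid, y), SpectralCurve(grid, z))


_CMFS = cie_1931_cmfs()

# linear sRGB primaries, D65 white (IEC 61966-2-1)
_XYZ_TO_RGB = np.array([
    [3.2406, -1.5372, -0.4986],
    [-0.9689, 1.8758, 0.0415],
    [0.0557, -0.2040, 1.0570],
])


@dataclass(frozen=True)
class TristimulusColor:
    X: float
    Y: float
    Z: float
    rgb: tuple[float, float, float]
    out_of_gamut: bool = False

    @property
    def chromaticity(self) -> tuple[float, float]:
        s = self.X + self.Y + self.Z
        if s == 0:
            return (float("nan"), float("nan"))
        return (self.X / s, self.Y / s)


def _srgb_transfer(linear: np.ndarray) -> np.ndarray:
    a = 0.055
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        (1 + a) * np.power(np.clip(linear, 0.0, None), 1 / 2.4) - a,
    )


def xyz_to_srgb(X: float, Y: float, Z: float) -> tuple[tuple[float, float, float], bool]:
    """XYZ (Y on a 0-1 scale) -> 8-bit sRGB triple + out-of-gamut flag."""
    lin = _XYZ_TO_RGB @ np.array([X, Y, Z])
    oog = bool(np.any(lin < -1e-9) or np.any(lin > 1 + 1e-9))
    lin = np.clip(lin, 0.0, 1.0)
    rgb = 255.0 * _srgb_transfer(lin)
    return (float(rgb[0]), float(rgb[1]), float(rgb[2])), oog


def spectrum_to_xyz(
    radiance: SpectralCurve, y_scale: float | None = None
) -> TristimulusColor:
    """Integrate a radiance spectrum against the 2-degree observer.

    ``y_scale`` divides the raw tristimulus values before the sRGB
    transform (use the Y of a reference white/beige patch so that patch
    renders at full brightness); by default the spectrum's own Y is used,
    so any nonzero spectrum renders at maximal lightness.
    """
    xbar, ybar, zbar = _CMFS
    lo = max(radiance.wavelengths[0], xbar.wavelengths[0])
    hi = min(radiance.wavelengths[-1], xbar.wavelengths[-1])
    if lo >= hi:
        warnings.warn("radiance does not overlap the observer range; zero color",
                      stacklevel=2)
        return TristimulusColor(0.0, 0.0, 0.0, (0.0, 0.0, 0.0))
    X = quantum_catch(xbar, radiance)
    Y = quantum_catch(ybar, radiance)
    Z = quantum_catch(zbar, radiance)
    if X == Y == Z == 0.0:
        return TristimulusColor(0.0, 0.0, 0.0, (0.0, 0.0, 0.0))
    scale = float(y_scale) if y_scale is not None else Y
    if scale <= 0:
        raise ValueError("y_scale must be positive")
    rgb, oog = xyz_to_srgb(X / scale, Y / scale, Z / scale)
    return TristimulusColor(X, Y, Z, rgb, oog)


def monochromat_lightness(
    radiance: SpectralCurve, pigment: VisualPigmentTemplate
) -> float:
    """Lightness seen by a single-pigment observer: the quantum catch.

    Unnormalized; callers normalize per scene (e.g. brightest patch -> 255).
    Metameric by construction: equal catches give equal lightness.
    """
    return quantum_catch(template_absorbance(pigment), radiance)


def patch_contrast_ratio(
    beige_radiance: SpectralCurve,
    dark_radiance: SpectralCurve,
    observer,
) -> float:
    """Beige/dark intensity ratio for a monochromatic observer.

    ``observer`` is a VisualPigmentTemplate or any sensitivity
    SpectralCurve (e.g. a camera channel). The beige patch is the
    normalization reference (rendered at 255), so the ratio is
    I_beige / I_dark; an all-dark patch yields +inf.
    """
    if isinstance(observer, VisualPigmentTemplate):
        sens = template_absorbance(observer)
    else:
        sens = observer
    ib = quantum_catch(sens, beige_radiance)
    id_ = quantum_catch(sens, dark_radiance)
    if ib <= 0:
        raise ValueError("beige patch catch must be positive for normalization")
    if id_ == 0:
        warnings.warn("dark patch catch is zero; contrast ratio is infinite",
                      stacklevel=2)
        return float("inf")
    return ib / id_


def render_patch_pair(
    beige_radiance: SpectralCurve,
    dark_radiance: SpectralCurve,
    observer,
    white_normalize: bool = True,
):
    """Render a beige/dark patch pair to 8-bit values for an observer.

    Monochromat / camera-channel observers give gray triples with beige at
    exactly (255, 255, 255).  The 'human' observer gives sRGB triples; with
    ``white_normalize`` the beige patch is adjusted to white channel-wise
    (von Kries-style) and the dark patch is scaled identically.
    Returns (beige_rgb, dark_rgb, ratio).
    """
    if observer == "human":
        yb = spectrum_to_xyz(beige_radiance).Y
        cb = spectrum_to_xyz(beige_radiance, y_scale=yb)
        cd = spectrum_to_xyz(dark_radiance, y_scale=yb)
        if white_normalize:
            gains = [255.0 / c if c > 0 else 0.0 for c in cb.rgb]
            beige = tuple(min(255.0, c * g) for c, g in zip(cb.rgb, gains))
            dark = tuple(min(255.0, c * g) for c, g in zip(cd.rgb, gains))
        else:
            beige, dark = cb.rgb, cd.rgb
        ratio = yb / spectrum_to_xyz(dark_radiance).Y if cd.Y > 0 else float("inf")
        return beige, dark, ratio
    ratio = patch_contrast_ratio(beige_radiance, dark_radiance, observer)
    dark_val = 0.0 if ratio == float("inf") else 255.0 / ratio
    return (255.0, 255.0, 255.0), (dark_val,) * 3, ratio
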