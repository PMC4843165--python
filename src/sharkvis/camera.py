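"""Camera simulation: filter stacks over an RGB sensor.

The "shark-eye" rig approximates a catshark's single-pigment spectral
window with glass: a blue-green band-pass (Wratten 44A-style), a 575 nm
short-pass and a 400 nm long-pass stacked over the lens, keeping only the
blue channel of the sensor.  The fluorescence rig instead uses a royal-blue
excitation source behind a 450/70 nm band-pass and a 514 nm long-pass
emission filter on the sensor.

Packaged curves are idealized (smoothed-step cut filters with a 10 nm
transition, Gaussian-ish sensor channels and band-passes) and replaceable
with measured two-column CSVs; an imaging step is just the quantum catch of
each effective channel against the scene radiance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contrast import quantum_catch
from .spectra import CANONICAL_GRID, SpectralCurve, validate_fraction

__all__ = [
    "FilterStack",
    "CameraResponse",
    "effective_response",
    "image_patch",
    "default_sensor",
    "shark_eye_stack",
    "fluorescence_emission_stack",
    "royal_blue_source",
    "long_pass",
    "short_pass",
    "band_pass",
]


def _smoothstep(lam: np.ndarray, cutoff: float, transition: float, rising: bool):
    """Logistic edge with ~``transition`` nm between 12% and 88% points."""
    t = (lam - cutoff) / (transition / 4.0)
    s = 1.0 / (1.0 + np.exp(-t))
    return s if rising else 1.0 - s


def long_pass(cutoff: float, transition: float = 10.0,
              grid: np.ndarray = CANONICAL_GRID) -> SpectralCurve:
    grid = np.asarray(grid, dtype=float)
    return SpectralCurve(grid, _smoothstep(grid, cutoff, transition, rising=True))


def short_pass(cutoff: float, transition: float = 10.0,
               grid: np.ndarray = CANONICAL_GRID) -> SpectralCurve:
    grid = np.asarray(grid, dtype=float)
    return SpectralCurve(grid, _smoothstep(grid, cutoff, transition, rising=False))


def band_pass(center: float, fwhm: float, peak: float = 1.0,
              grid: np.ndarray = CANONICAL_GRID) -> SpectralCurve:
    grid = np.asarray(grid, dtype=float)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return SpectralCurve(grid, peak * np.exp(-((grid - center) ** 2) / (2 * sigma**2)))


def ideal_long_pass(cutoff: float, grid: np.ndarray = CANONICAL_GRID) -> SpectralCurve:
    """Hard-edged long-pass (exactly zero below the cutoff)."""
    grid = np.asarray(grid, dtype=float)
    return SpectralCurve(grid, (grid >= cutoff).astype(float))


@dataclass(frozen=True)
class FilterStack:
    """Ordered transmission filters; combined transmission is their product."""

    filters: tuple[SpectralCurve, ...]

    def __post_init__(self) -> None:
        for i, f in enumerate(self.filters):
            validate_fraction(f, f"filter {i} transmission")

    def transmission(self, grid: np.ndarray = CANONICAL_GRID) -> SpectralCurve:
        grid = np.asarray(grid, dtype=float)
        t = np.ones_like(grid)
        for f in self.filters:
            t = t * f(grid)
        return SpectralCurve(grid, t)


@dataclass(frozen=True)
class CameraResponse:
    """Named channel spectral sensitivities (typically R, G, B)."""

    channels: dict

    def channel(self, name: str) -> SpectralCurve:
        return self.channels[name]


def default_sensor(grid: np.ndarray = CANONICAL_GRID) -> CameraResponse:
    """Representative cinema-sensor RGB sensitivities (Gaussian channels)."""
    return CameraResponse({
        "R": band_pass(600.0, 100.0, 0.9, grid),
        "G": band_pass(540.0, 95.0, 1.0, grid),
        "B": band_pass(460.0, 85.0, 0.95, grid),
    })


def wratten_44a(grid: np.ndarray = CANONICAL_GRID) -> SpectralCurve:
    """Idealized Wratten 44A blue-green band-pass (digitized shape)."""
    return band_pass(490.0, 90.0, 0.62, grid)


def shark_eye_stack(grid: np.ndarray = CANONICAL_GRID) -> FilterStack:
    """44A band-pass + 575 nm short-pass + 400 nm long-pass."""
    return FilterStack((
        wratten_44a(grid),
        short_pass(575.0, 10.0, grid),
        long_pass(400.0, 10.0, grid),
    ))


def fluorescence_emission_stack(grid: np.ndarray = CANONICAL_GRID) -> FilterStack:
    """514 nm long-pass emission filter for fluorescence imaging."""
    return FilterStack((ideal_long_pass(514.0, grid),))


def royal_blue_source(
    amplitude: float = 1e18, grid: np.ndarray = CANONICAL_GRID
) -> SpectralCurve:
    """Royal-blue LED (Gaussian, 450 nm centre, 70 nm FWHM) through a
    450/70 nm interference band-pass."""
    led = band_pass(450.0, 70.0, 1.0, grid)
    bp = band_pass(450.0, 70.0, 0.95, grid)
    return SpectralCurve(grid, amplitude * led.values * bp.values)


def effective_response(cam: CameraResponse, stack: FilterStack) -> CameraResponse:
    """Each channel multiplied pointwise by the stack transmission."""
    out = {}
    for name, ch in cam.channels.items():
        t = stack.transmission(ch.wavelengths)
        out[name] = SpectralCurve(ch.wavelengths, ch.values * t.values)
    return CameraResponse(out)


def image_patch(cam: CameraResponse, radiance: SpectralCurve) -> dict:
    """Per-channel intensities: quantum catch of each channel sensitivity."""
    return {
        name: quantum_catch(ch, radiance) for name, ch in cam.channels.items()
    }
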