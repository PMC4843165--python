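"""Excitation-emission matrix (EEM) model of fluorescent skin radiance.

Skin fluorescence is linear in the exciting light: the emitted spectrum is
the EEM (emitted photons per excitation photon per nm of emission) applied
to the incident excitation spectrum,

    L_em(lambda_em) = sum_ex  EEM(lambda_ex, lambda_em) * E(lambda_ex) * dlambda_ex.

Physical constraints enforced on every EEM: efficiencies are nonnegative,
anti-Stokes entries (emission at or below the excitation wavelength) are
zero, and the total photons emitted per excitation photon never exceed the
quantum-efficiency bound of 1.

A skin patch combines a reflectance curve with an EEM; its radiance toward
a viewer under a given light field is the Lambertian-reflected component
plus the fluorescent component, both divided by pi (diffuse emitter; the
factor cancels in all contrast ratios).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .light import LightField, downwelling
from .spectra import SpectralCurve, resample, validate_fraction

__all__ = ["EEM", "SkinPatch", "emission_under_excitation", "skin_radiance"]


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Per-sample weights so that w @ f equals the trapezoidal integral."""
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w


@dataclass(frozen=True)
class EEM:
    """Excitation x emission fluorescence efficiency matrix.

    ``efficiency[i, j]`` is emitted photons per excitation photon per nm of
    emission, for excitation ``excitation_grid[i]`` and emission
    ``emission_grid[j]``.
    """

    excitation_grid: np.ndarray
    emission_grid: np.ndarray
    efficiency: np.ndarray

    def __post_init__(self) -> None:
        ex = np.asarray(self.excitation_grid, dtype=float)
        em = np.asarray(self.emission_grid, dtype=float)
        eff = np.asarray(self.efficiency, dtype=float)
        if ex.ndim != 1 or em.ndim != 1:
            raise ValueError("EEM grids must be 1-D")
        if not (np.all(np.diff(ex) > 0) and np.all(np.diff(em) > 0)):
            raise ValueError("EEM grids must be strictly increasing")
        if eff.shape != (ex.size, em.size):
            raise ValueError(
                f"efficiency shape {eff.shape} does not match grids "
                f"({ex.size} excitation x {em.size} emission)"
            )
        if np.any(eff < 0) or not np.all(np.isfinite(eff)):
            raise ValueError("EEM efficiencies must be finite and nonnegative")
        # Stokes constraint: no emission at or below the excitation wavelength
        anti = em[None, :] <= ex[:, None]
        if np.any(eff[anti] > 0):
            warnings.warn(
                "anti-Stokes EEM entries (emission <= excitation) zeroed",
                stacklevel=2,
            )
            eff = np.where(anti, 0.0, eff)
        # Quantum-efficiency bound: photons out per photon in, per excitation
        qsum = eff @ _trapezoid_weights(em)
        if np.any(qsum > 1.0 + 1e-9):
            raise ValueError(
                f"quantum-efficiency bound violated: max photons emitted per "
                f"excitation photon = {qsum.max():.3g} > 1"
            )
        object.__setattr__(self, "excitation_grid", ex)
        object.__setattr__(self, "emission_grid", em)
        object.__setattr__(self, "efficiency", eff)

    def quantum_yield(self) -> np.ndarray:
        """Photons emitted per excitation photon, per excitation wavelength."""
        return self.efficiency @ _trapezoid_weights(self.emission_grid)

    def scaled(self, factor: float) -> "EEM":
        if factor < 0:
            raise ValueError("EEM scale factor must be nonnegative")
        return EEM(self.excitation_grid, self.emission_grid, self.efficiency * factor)

    @classmethod
    def zero(cls, excitation_grid, emission_grid) -> "EEM":
        ex = np.asarray(excitation_grid, dtype=float)
        em = np.asarray(emission_grid, dtype=float)
        return cls(ex, em, np.zeros((ex.size, em.size)))

    # -- matrix CSV: first row = emission grid, first column = excitation ---

    @classmethod
    def from_csv(cls, path) -> "EEM":
        raw = np.genfromtxt(path, delimiter=",", dtype=float)
        if raw.ndim != 2 or raw.shape[0] < 2 or raw.shape[1] < 2:
            raise ValueError(f"{path}: EEM CSV needs a header row and column")
        return cls(raw[1:, 0], raw[0, 1:], raw[1:, 1:])

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("," + ",".join(f"{x:g}" for x in self.emission_grid) + "\n")
            for ex, row in zip(self.excitation_grid, self.efficiency):
                fh.write(f"{ex:g}," + ",".join(f"{v:.8g}" for v in row) + "\n")


def emission_under_excitation(eem: EEM, excitation: SpectralCurve) -> SpectralCurve:
    """Fluorescent emission spectrum produced by an excitation spectrum."""
    lo = max(eem.excitation_grid[0], excitation.wavelengths[0])
    hi = min(eem.excitation_grid[-1], excitation.wavelengths[-1])
    if lo > hi:
        raise ValueError("excitation spectrum and EEM excitation grid are disjoint")
    exc = resample(excitation, eem.excitation_grid)
    w_ex = _trapezoid_weights(eem.excitation_grid)
    em_vals = (exc.values * w_ex) @ eem.efficiency
    return SpectralCurve(eem.emission_grid, np.clip(em_vals, 0.0, None))


@dataclass(frozen=True)
class SkinPatch:
    """A skin region: reflectance in [0,1] plus its fluorescence EEM."""

    label: str
    reflectance: SpectralCurve
    eem: EEM

    def __post_init__(self) -> None:
        validate_fraction(self.reflectance, f"reflectance of patch {self.label!r}")

    def without_fluorescence(self) -> "SkinPatch":
        return SkinPatch(
            self.label,
            self.reflectance,
            EEM.zero(self.eem.excitation_grid, self.eem.emission_grid),
        )


def skin_radiance(patch: SkinPatch, lf: LightField) -> SpectralCurve:
    """Patch radiance toward the viewer: (reflected + fluoresced) / pi."""
    ed = downwelling(lf)
    grid = ed.wavelengths
    reflected = resample(patch.reflectance, grid).values * ed.values / np.pi
    fluo = resample(emission_under_excitation(patch.eem, ed), grid).values / np.pi
    return SpectralCurve(grid, reflected + fluo)
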