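"""Canonical spectral data type and the small numerics shared by every stage.

All quantities in this package are sampled functions of wavelength in
nanometres: absorbance (unitless), downwelling irradiance
(photons m^-2 s^-1 nm^-1), reflectance and filter transmission (fractions in
[0, 1]).  A :class:`SpectralCurve` holds one such function on a strictly
increasing wavelength grid; integration is trapezoidal and resampling is
linear with zero outside the original support (conservative for the
quantum-catch integrals downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CANONICAL_GRID",
    "SpectralCurve",
    "resample",
    "integrate",
]

#: Internal working grid: 300-700 nm at 1 nm. All printed spectral features of
#: the system under study (pigment bands, skin emission, underwater light)
#: fall inside this window.
CANONICAL_GRID = np.arange(300.0, 700.0 + 1.0, 1.0)


@dataclass(frozen=True)
class SpectralCurve:
    """A nonnegative sampled function of wavelength.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelengths, nm.
    values
        Nonnegative samples, same length as ``wavelengths``. Units depend on
        what the curve represents (absorbance, irradiance, fraction, ...).
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or v.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if w.size != v.size:
            raise ValueError(
                f"length mismatch: {w.size} wavelengths vs {v.size} values"
            )
        if w.size == 0:
            raise ValueError("empty spectral curve")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if np.any(v < 0):
            raise ValueError("spectral values must be nonnegative")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "values", v)

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return self.wavelengths.size

    def __call__(self, lam) -> np.ndarray:
        """Linear interpolation at ``lam``; zero outside the support."""
        return np.interp(lam, self.wavelengths, self.values, left=0.0, right=0.0)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    @property
    def peak_wavelength(self) -> float:
        """Wavelength of the maximum sample (lowest index on ties)."""
        return float(self.wavelengths[int(np.argmax(self.values))])

    @property
    def max_value(self) -> float:
        return float(self.values.max())

    # -- constructors ------------------------------------------------------

    @classmethod
    def constant(cls, value: float, grid: np.ndarray = CANONICAL_GRID) -> "SpectralCurve":
        grid = np.asarray(grid, dtype=float)
        return cls(grid, np.full(grid.shape, float(value)))

    @classmethod
    def from_function(cls, fn, grid: np.ndarray = CANONICAL_GRID) -> "SpectralCurve":
        grid = np.asarray(grid, dtype=float)
        return cls(grid, np.asarray(fn(grid), dtype=float))

    # -- algebra on a shared grid ------------------------------------------

    def on(self, grid: np.ndarray) -> "SpectralCurve":
        return resample(self, grid)

    def scaled(self, factor: float) -> "SpectralCurve":
        if factor < 0:
            raise ValueError("scale factor must be nonnegative")
        return SpectralCurve(self.wavelengths, self.values * factor)

    def _binary(self, other: "SpectralCurve", op) -> "SpectralCurve":
        if not np.array_equal(self.wavelengths, other.wavelengths):
            raise ValueError("curves must share a wavelength grid; resample first")
        return SpectralCurve(self.wavelengths, op(self.values, other.values))

    def __add__(self, other: "SpectralCurve") -> "SpectralCurve":
        return self._binary(other, np.add)

    def __mul__(self, other):
        if isinstance(other, SpectralCurve):
            return self._binary(other, np.multiply)
        return self.scaled(float(other))

    __rmul__ = __mul__

    def normalized(self) -> "SpectralCurve":
        """Scale so the maximum sample is 1.0."""
        m = self.max_value
        if m <= 0:
            raise ValueError("cannot normalize an all-zero curve")
        return SpectralCurve(self.wavelengths, self.values / m)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "SpectralCurve":
        """Read the package-standard two-column CSV (wavelength_nm,value)."""
        arr = np.genfromtxt(path, delimiter=",", names=True, dtype=float)
        if arr.dtype.names is None or len(arr.dtype.names) < 2:
            raise ValueError(f"{path}: expected header 'wavelength_nm,value'")
        w_name, v_name = arr.dtype.names[:2]
        return cls(np.atleast_1d(arr[w_name]), np.atleast_1d(arr[v_name]))

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("wavelength_nm,value\n")
            for w, v in zip(self.wavelengths, self.values):
                fh.write(f"{w:.6g},{v:.10g}\n")


def resample(curve: SpectralCurve, grid) -> SpectralCurve:
    """Linearly interpolate ``curve`` onto ``grid``; zero outside the support.

    Idempotent when ``grid`` equals the curve's own grid.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("resample grid is empty")
    if grid.ndim != 1 or not np.all(np.diff(grid) > 0):
        raise ValueError("resample grid must be 1-D strictly increasing")
    return SpectralCurve(grid, curve(grid))


def integrate(curve: SpectralCurve) -> float:
    """Trapezoidal integral of the curve over its support (units x nm)."""
    if len(curve) < 2:
        raise ValueError("integration requires at least two samples")
    return float(np.trapezoid(curve.values, curve.wavelengths))


def validate_fraction(curve: SpectralCurve, what: str = "curve") -> SpectralCurve:
    """Check a reflectance/transmission curve stays within [0, 1]."""
    if curve.values.max(initial=0.0) > 1.0 + 1e-12:
        raise ValueError(f"{what} exceeds 1.0 (max {curve.values.max():.4g})")
    return curve
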