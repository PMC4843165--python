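"""Visual pigment absorbance templates (vitamin A1 and A2 chromophores).

Rod and cone visual pigments have stereotyped absorbance spectra: once the
wavelength of maximum absorbance (lambda_max) and the chromophore class are
fixed, the whole normalized curve follows from a standard template.  This
module implements the Govardovskii et al. (2000) rhodopsin/porphyropsin
parameterization — an alpha band that is a sum-of-exponentials function of
the normalized frequency x = lambda_max / lambda, plus a Gaussian beta
(cis-peak) band in the UV.  A2 (3,4-didehydroretinal) pigments are broader
and have a heavier long-wave tail than A1 (retinal) pigments with the same
lambda_max.

Coefficient provenance: alpha- and beta-band constants below are the
published Govardovskii et al. (2000, Visual Neuroscience 17:509-528) values
for the A1 and A2 templates; they are not refit here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectra import CANONICAL_GRID, SpectralCurve

__all__ = [
    "VisualPigmentTemplate",
    "HalfMaxRange",
    "template_absorbance",
    "half_max_range",
    "raw_template",
]

LAMBDA_MAX_RANGE = (330.0, 650.0)


def _alpha_a1(lam, lmax):
    lam = np.asarray(lam, dtype=float)
    lmax = np.asarray(lmax, dtype=float)
    x = lmax / lam
    a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
    with np.errstate(over="ignore"):
        den = (
            np.exp(69.7 * (a - x))
            + np.exp(28.0 * (0.922 - x))
            + np.exp(-14.9 * (1.104 - x))
            + 0.674
        )
    return 1.0 / den


def _beta_a1(lam, lmax):
    lam = np.asarray(lam, dtype=float)
    lmax = np.asarray(lmax, dtype=float)
    lmb = 189.0 + 0.315 * lmax
    b = -40.5 + 0.195 * lmax
    return 0.26 * np.exp(-(((lam - lmb) / b) ** 2))


def _alpha_a2(lam, lmax):
    lam = np.asarray(lam, dtype=float)
    lmax = np.asarray(lmax, dtype=float)
    x = lmax / lam
    a = 0.875 + 0.0268 * np.exp((lmax - 665.0) / 40.7)
    A = 62.7 + 1.834 * np.exp((lmax - 625.0) / 54.2)
    with np.errstate(over="ignore"):
        den = (
            np.exp(A * (a - x))
            + np.exp(20.85 * (0.9101 - x))
            + np.exp(-10.37 * (1.1123 - x))
            + 0.5343
        )
    return 1.0 / den


def _beta_a2(lam, lmax):
    lam = np.asarray(lam, dtype=float)
    lmax = np.asarray(lmax, dtype=float)
    lmb = 216.7 + 0.287 * lmax
    b = 317.0 - 1.149 * lmax + 0.00124 * lmax**2
    return 0.37 * np.exp(-(((lam - lmb) / b) ** 2))


_BANDS = {"A1": (_alpha_a1, _beta_a1), "A2": (_alpha_a2, _beta_a2)}


def raw_template(lam, lmax, chromophore: str = "A1"):
    """Unnormalized alpha+beta template absorbance; broadcasts lam vs lmax."""
    try:
        alpha, beta = _BANDS[chromophore]
    except KeyError:
        raise ValueError(f"unknown chromophore {chromophore!r}; expected A1 or A2")
    return alpha(lam, lmax) + beta(lam, lmax)


def _peak_value(lmax, chromophore: str) -> np.ndarray:
    """Template maximum, for normalization.

    The sum-of-exponentials alpha band peaks within a fraction of a nm of
    lambda_max and very slightly above 1; the true maximum is located on a
    dense 0.01 nm grid around lambda_max so that normalization does not
    depend on the caller's sampling grid.
    """
    lmax = np.atleast_1d(np.asarray(lmax, dtype=float))
    dense = np.arange(-3.0, 3.0 + 0.01, 0.01)
    vals = raw_template(lmax[:, None] + dense[None, :], lmax[:, None], chromophore)
    return vals.max(axis=1)


@dataclass(frozen=True)
class VisualPigmentTemplate:
    """A visual pigment defined by lambda_max (nm) and chromophore class."""

    lambda_max: float
    chromophore: str = "A1"

    def __post_init__(self) -> None:
        lo, hi = LAMBDA_MAX_RANGE
        if not (lo <= self.lambda_max <= hi):
            raise ValueError(
                f"lambda_max {self.lambda_max} nm outside template validity "
                f"range [{lo}, {hi}]"
            )
        if self.chromophore not in _BANDS:
            raise ValueError(
                f"unknown chromophore {self.chromophore!r}; expected A1 or A2"
            )

    def absorbance(self, grid: np.ndarray = CANONICAL_GRID) -> SpectralCurve:
        return template_absorbance(self, grid)


def template_absorbance(
    t: VisualPigmentTemplate, grid: np.ndarray = CANONICAL_GRID
) -> SpectralCurve:
    """Normalized template absorbance curve on ``grid`` (max value 1.0)."""
    grid = np.asarray(grid, dtype=float)
    vals = raw_template(grid, t.lambda_max, t.chromophore)
    vals = vals / _peak_value(t.lambda_max, t.chromophore)[0]
    # guard rounding: keep the sampled maximum at exactly <= 1
    vals = np.clip(vals, 0.0, 1.0)
    return SpectralCurve(grid, vals)


@dataclass(frozen=True)
class HalfMaxRange:
    """Outermost wavelengths where a unimodal curve crosses half its maximum.

    ``lo_clipped``/``hi_clipped`` flag sides where the curve never falls
    below half maximum inside its support, in which case the support
    boundary is reported.
    """

    lambda_lo: float
    lambda_hi: float
    lo_clipped: bool = False
    hi_clipped: bool = False

    @property
    def width(self) -> float:
        return self.lambda_hi - self.lambda_lo


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def half_max_range(curve: SpectralCurve, smooth_window: int = 1) -> HalfMaxRange:
    """Locate the half-maximum crossings of a unimodal absorbance curve.

    Crossings are found by linear interpolation between the bracketing
    samples, scanning outward-in so the *outermost* crossings are returned.
    ``smooth_window`` applies a centred running mean first (use 5 for noisy
    measured scans; crossing detection on raw noise is unstable).
    """
    w = curve.wavelengths
    v = _smooth(curve.values, smooth_window)
    vmax = v.max()
    if vmax <= 0:
        raise ValueError("half_max_range requires a curve with positive maximum")
    half = 0.5 * vmax
    ipk = int(np.argmax(v))

    lo, lo_clipped = float(w[0]), True
    for i in range(ipk):  # first upward crossing from the left
        if v[i] < half <= v[i + 1]:
            frac = (half - v[i]) / (v[i + 1] - v[i])
            lo, lo_clipped = float(w[i] + frac * (w[i + 1] - w[i])), False
            break

    hi, hi_clipped = float(w[-1]), True
    for i in range(len(w) - 1, ipk, -1):  # first downward crossing from the right
        if v[i] < half <= v[i - 1]:
            frac = (half - v[i - 1]) / (v[i] - v[i - 1])
            hi, hi_clipped = float(w[i - 1] + frac * (w[i] - w[i - 1])), False
            break

    if lo_clipped or hi_clipped:
        warnings.warn(
            "half-maximum not crossed on one side; reporting support boundary",
            stacklevel=2,
        )
    return HalfMaxRange(lo, hi, lo_clipped, hi_clipped)
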