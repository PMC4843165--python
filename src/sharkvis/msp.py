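"""Microspectrophotometry (MSP) analysis: scan interleaving, Gaussian peak
estimation, and lambda_max determination by template sliding.

The measurement protocol records a down-scan on even nanometres and a return
(up-) scan on odd nanometres; the two are interleaved into one absorbance
spectrum.  Analysis then proceeds in two stages, mirroring standard MSP
practice:

1. an unnormalized Gaussian (amplitude, centre, width, offset) is fit to the
   raw samples around the spectral peak (40 points on either side of the raw
   argmax by default) and its analytic maximum gives the initial peak
   estimate x_max;
2. A1 and A2 visual-pigment templates are "slid" along the wavelength axis
   around x_max and the best least-squares fit to the normalized scan gives
   lambda_max and the chromophore class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .pigments import _peak_value, raw_template
from .spectra import SpectralCurve

__all__ = ["MSPScan", "FitResult", "interleave", "initial_peak", "fit_template"]


@dataclass(frozen=True)
class MSPScan:
    """An interleaved MSP absorbance scan."""

    down_scan: SpectralCurve
    up_scan: SpectralCurve | None
    merged: SpectralCurve


def interleave(down: SpectralCurve, up: SpectralCurve | None) -> MSPScan:
    """Merge a down-scan and a return scan into one spectrum.

    Source samples are preserved unchanged; the merged grid is the sorted
    union of the two grids. Duplicate wavelengths are an error (the scans
    sample disjoint even/odd nm).
    """
    if up is None or len(up) == 0:
        return MSPScan(down, up, down)
    w = np.concatenate([down.wavelengths, up.wavelengths])
    v = np.concatenate([down.values, up.values])
    order = np.argsort(w, kind="stable")
    w, v = w[order], v[order]
    if np.any(np.diff(w) == 0):
        dup = w[:-1][np.diff(w) == 0]
        raise ValueError(f"duplicate wavelengths in down/up scans: {dup[:5]}")
    return MSPScan(down, up, SpectralCurve(w, v))


def _gaussian(lam, amp, center, sigma, offset):
    return amp * np.exp(-((lam - center) ** 2) / (2.0 * sigma**2)) + offset


def _gaussian_peak_fit(curve: SpectralCurve, window: int = 40):
    """Fit a Gaussian to the ``window`` samples on each side of the argmax.

    Returns (center, peak_value, popt). The analytic maximum of the fitted
    Gaussian is its centre.
    """
    w, v = curve.wavelengths, curve.values
    n = len(w)
    if n < 2 * window + 1:
        raise ValueError(
            f"scan has {n} samples; need at least {2 * window + 1} for the "
            f"Gaussian peak fit (window={window})"
        )
    i = int(np.argmax(v))
    if i == 0 or i == n - 1:
        raise ValueError("peak outside scan range")
    lo, hi = max(0, i - window), min(n, i + window + 1)
    ww, vv = w[lo:hi], v[lo:hi]
    p0 = (float(v[i] - vv.min()), float(w[i]), 30.0, float(vv.min()))
    popt, _ = curve_fit(_gaussian, ww, vv, p0=p0, maxfev=20000)
    amp, center, sigma, offset = popt
    if amp <= 0 or not np.isfinite(center):
        raise ValueError("Gaussian peak fit failed (non-positive amplitude)")
    return float(center), float(amp + offset), popt


def initial_peak(scan: MSPScan, window: int = 40) -> float:
    """Initial peak estimate x_max: centre of the Gaussian fit at the argmax."""
    center, _, _ = _gaussian_peak_fit(scan.merged, window)
    return center


@dataclass(frozen=True)
class FitResult:
    """Outcome of template sliding on a normalized MSP scan."""

    lambda_max_hat: float
    chromophore: str
    residual_ss: float
    x_max_initial: float


def _linear_detrend(curve: SpectralCurve) -> SpectralCurve:
    """Remove the straight line through the two support endpoints (optional
    fallback when instrument baseline correction is imperfect)."""
    w, v = curve.wavelengths, curve.values
    line = v[0] + (v[-1] - v[0]) * (w - w[0]) / (w[-1] - w[0])
    return SpectralCurve(w, np.clip(v - line, 0.0, None))


def fit_template(
    scan: MSPScan,
    chromophores: tuple[str, ...] = ("A1", "A2"),
    window: int = 40,
    search_halfwidth: float = 30.0,
    step: float = 0.1,
    detrend: bool = False,
) -> FitResult:
    """Find lambda_max by sliding A1/A2 templates and least-squares fitting.

    The scan is normalized by the fitted Gaussian peak value (robust to a
    single noisy maximum sample), candidate lambda_max values are scanned on
    a ``step`` nm grid within ``search_halfwidth`` of the initial peak for
    each chromophore, and the global least-squares minimum is returned. Ties
    between chromophores (residual difference < 1e-9) resolve to A1.
    """
    merged = _linear_detrend(scan.merged) if detrend else scan.merged
    x0, peak_value, _ = _gaussian_peak_fit(merged, window)
    if peak_value <= 0:
        raise ValueError("non-positive fitted peak; cannot normalize scan")
    w = merged.wavelengths
    y = merged.values / peak_value

    candidates = np.arange(x0 - search_halfwidth, x0 + search_halfwidth + step, step)
    best: FitResult | None = None
    for chrom in chromophores:
        # (n_candidates, n_samples) template matrix, each row normalized to 1
        tmpl = raw_template(w[None, :], candidates[:, None], chrom)
        tmpl = tmpl / _peak_value(candidates, chrom)[:, None]
        ssr = np.square(tmpl - y[None, :]).sum(axis=1)
        if not np.any(np.isfinite(ssr)):
            raise ValueError("all template residuals non-finite")
        k = int(np.nanargmin(ssr))
        res = FitResult(float(candidates[k]), chrom, float(ssr[k]), x0)
        if best is None or res.residual_ss < best.residual_ss - 1e-9:
            best = res
    assert best is not None
    return best
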