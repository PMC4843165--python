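"""Quantum catch, luminosity contrast, detectability, and the optimal-pigment
locus for a monochromatic underwater observer.

A single-pigment (rod monochromat) eye can only compare photon catches, so
target detection against the background spacelight reduces to a luminosity
contrast task: the Weber contrast of quantum catches,
C = (Q_target - Q_background) / Q_background, compared against a
photoreceptor noise threshold, with an absolute minimum catch below which
nothing is seen.

The optimal-pigment locus follows the sensitivity-hypothesis logic: ambient
intensity is notionally reduced until detection fails, so among pigments
whose contrast clears the noise threshold, the one that keeps the largest
background catch (i.e. whose absorbance envelope best overlaps the
spacelight) stays detectable to the greatest depth/dimming and is optimal.
Operationally the locus ranks candidate lambda_max by |Weber contrast|,
breaking near-ties (relative 1e-9, which includes the spectrally neutral
gray-target case where contrast is exactly flat in lambda_max) by larger
background quantum catch, then by lowest lambda_max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fluorescence import SkinPatch, skin_radiance
from .light import LightField, WaterType, downwelling, flat_surface, spacelight
from .pigments import VisualPigmentTemplate, template_absorbance
from .spectra import CANONICAL_GRID, SpectralCurve, resample

__all__ = [
    "ThresholdModel",
    "ContrastResult",
    "PigmentLocus",
    "quantum_catch",
    "weber_contrast",
    "michelson_contrast",
    "detectable",
    "pigment_locus",
    "depth_detectability_profile",
    "intensity_floor",
]


def quantum_catch(sensitivity: SpectralCurve, radiance: SpectralCurve) -> float:
    """Photon catch: trapezoidal integral of sensitivity x radiance.

    Both curves are brought onto the finer common grid over the overlap of
    their supports; disjoint supports yield 0 with a warning.
    """
    lo = max(sensitivity.wavelengths[0], radiance.wavelengths[0])
    hi = min(sensitivity.wavelengths[-1], radiance.wavelengths[-1])
    if lo >= hi:
        warnings.warn("sensitivity and radiance supports are disjoint; catch = 0",
                      stacklevel=2)
        return 0.0
    step = min(
        np.diff(sensitivity.wavelengths).min(), np.diff(radiance.wavelengths).min()
    )
    grid = np.arange(lo, hi + step / 2, step)
    s = sensitivity(grid)
    r = radiance(grid)
    return float(np.trapezoid(s * r, grid))


def weber_contrast(q_target: float, q_background: float) -> float:
    """(Q_t - Q_b) / Q_b; requires positive background catch."""
    if q_background <= 0:
        raise ValueError("Weber contrast requires a positive background catch")
    return (q_target - q_background) / q_background


def michelson_contrast(q_target: float, q_background: float) -> float:
    if q_target + q_background <= 0:
        raise ValueError("Michelson contrast requires positive total catch")
    return (q_target - q_background) / (q_target + q_background)


@dataclass(frozen=True)
class ThresholdModel:
    """Photoreceptor detection limits.

    min_contrast
        Minimum detectable |Weber contrast| (receptor signal-to-noise
        limit); default 0.02.
    min_catch
        Minimum background photon catch per integration time for the
        contrast channel to operate at all; default 1e6 photons (nominal —
        absolute radiometric scale is set by the surface spectrum).
    """

    min_contrast: float = 0.02
    min_catch: float = 1e6


DEFAULT_THRESHOLD = ThresholdModel()


def detectable(
    c: float, q_background: float, threshold: ThresholdModel = DEFAULT_THRESHOLD
) -> bool:
    """True iff the background catch and |contrast| both clear threshold."""
    return q_background >= threshold.min_catch and abs(c) >= threshold.min_contrast


def intensity_floor(
    c: float, q_background: float, threshold: ThresholdModel = DEFAULT_THRESHOLD
) -> float:
    """Largest intensity attenuation factor at which detection still works.

    Contrast is intensity-invariant, so scaling the ambient light by s
    leaves C unchanged while scaling the catches; detection survives down to
    s = min_catch / q_background. Returns 0 if the contrast itself is below
    threshold (never detectable), inf if q_background is 0... the caller
    guards that.
    """
    if abs(c) < threshold.min_contrast or q_background <= 0:
        return 0.0
    return q_background / threshold.min_catch


@dataclass(frozen=True)
class ContrastResult:
    depth: float
    q_target: float
    q_background: float
    weber: float
    detectable: bool


@dataclass(frozen=True)
class PigmentLocus:
    """Per-lambda_max contrast magnitudes and the optimal pigment."""

    lambda_grid: np.ndarray
    contrast_by_lambda: np.ndarray
    catch_by_lambda: np.ndarray
    optimum: float


DEFAULT_LOCUS_GRID = np.arange(400.0, 550.0 + 1.0, 1.0)


def _rank_locus(
    lambda_grid: np.ndarray,
    abs_contrast: np.ndarray,
    q_background: np.ndarray,
    rel_tol: float = 1e-9,
) -> int:
    """Index of the optimal pigment: max |contrast|, near-ties broken by
    larger background catch, then by lowest lambda_max."""
    cmax = abs_contrast.max()
    tied = abs_contrast >= cmax - rel_tol * max(cmax, 1e-300)
    idx = np.flatnonzero(tied)
    qb = q_background[idx]
    best = idx[qb >= qb.max() - rel_tol * max(qb.max(), 1e-300)]
    return int(best.min())


def pigment_locus(
    target_radiance: SpectralCurve,
    background_radiance: SpectralCurve,
    lambda_grid: np.ndarray = DEFAULT_LOCUS_GRID,
    chromophore: str = "A1",
    contrast: str = "weber",
) -> PigmentLocus:
    """Scan candidate lambda_max values for the best-discriminating pigment."""
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    metric = weber_contrast if contrast == "weber" else michelson_contrast
    cs = np.empty(lambda_grid.size)
    qbs = np.empty(lambda_grid.size)
    for i, lmax in enumerate(lambda_grid):
        t = template_absorbance(
            VisualPigmentTemplate(float(lmax), chromophore)
        )
        qt = quantum_catch(t, target_radiance)
        qb = quantum_catch(t, background_radiance)
        cs[i] = metric(qt, qb)
        qbs[i] = qb
    k = _rank_locus(lambda_grid, np.abs(cs), qbs)
    return PigmentLocus(lambda_grid, np.abs(cs), qbs, float(lambda_grid[k]))


def depth_detectability_profile(
    target: SkinPatch,
    background: SkinPatch | None,
    water: WaterType,
    depths,
    pigment: VisualPigmentTemplate,
    surface: SpectralCurve | None = None,
    threshold: ThresholdModel = DEFAULT_THRESHOLD,
    spacelight_k: float = 0.01,
) -> list[ContrastResult]:
    """Weber contrast and detectability of a patch at each depth.

    ``background`` is a second skin patch (patch-vs-patch contrast, the
    conspecific-pattern task); if None, the background is the water-column
    spacelight (target-vs-spacelight task).
    """
    depths = list(depths)
    if any(d < 0 for d in depths) or any(
        b <= a for a, b in zip(depths, depths[1:])
    ):
        raise ValueError("depths must be nonnegative and strictly increasing")
    if surface is None:
        surface = flat_surface()
    sens = template_absorbance(pigment)
    out: list[ContrastResult] = []
    for z in depths:
        lf = LightField(surface, water, float(z))
        lt = skin_radiance(target, lf)
        if background is None:
            lb = spacelight(lf, spacelight_k)
        else:
            lb = skin_radiance(background, lf)
        qt = quantum_catch(sens, lt)
        qb = quantum_catch(sens, lb)
        c = weber_contrast(qt, qb)
        out.append(ContrastResult(float(z), qt, qb, c, detectable(c, qb, threshold)))
    return out
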