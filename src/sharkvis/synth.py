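"""Synthetic fixtures defining the study conditions for every pipeline stage.

The generators emulate the measured inputs — noisy MSP absorbance scans
drawn from pigment templates, the two catshark species' skin
excitation-emission matrices, beige/dark patch reflectances, the
family-level phylogeny with fluorescent tips, and a structurally faithful
multi-gene alignment matrix — so every analysis runs without downloads.
All randomness is driven by explicit integer seeds; all fixture constants
live in ``data/fixture_params.yaml``.
"""

from __future__ import annotations

import functools
from importlib import resources

import numpy as np
import yaml

from .fluorescence import EEM, SkinPatch
from .msp import MSPScan, interleave
from .pigments import VisualPigmentTemplate, template_absorbance
from .spectra import SpectralCurve
from . import origins as _origins

__all__ = [
    "fixture_params",
    "gen_msp_scan",
    "gen_species_eem",
    "gen_patch_pair",
    "gen_family_tree_fixture",
    "gen_alignment_fixture",
    "SPECIES",
]

SPECIES = ("C_ventriosum", "S_retifer")


@functools.lru_cache(maxsize=1)
def fixture_params() -> dict:
    """The versioned fixture-parameter table (read-only)."""
    text = (resources.files("sharkvis") / "data" / "fixture_params.yaml").read_text()
    return yaml.safe_load(text)


def species_lambda_max(species: str) -> float:
    try:
        return float(fixture_params()["species"][species]["lambda_max_nm"])
    except KeyError:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")


# ---------------------------------------------------------------------------
# MSP scans


def gen_msp_scan(
    lambda_max: float,
    chromophore: str = "A1",
    noise_sd: float = 0.05,
    seed: int = 0,
    ar1_rho: float = 0.0,
) -> MSPScan:
    """Noisy MSP scan: template on even/odd nm down/up grids + noise.

    Gaussian i.i.d. absorbance noise by default; ``ar1_rho`` > 0 switches to
    an AR(1) wavelength-correlated noise stream (robustness testing). Noisy
    absorbances are truncated at zero (absorbance is nonnegative).
    Deterministic per seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    msp = fixture_params()["msp"]
    lo, hi = msp["scan_lo_nm"], msp["scan_hi_nm"]
    down_grid = np.arange(lo, hi + 1, 2, dtype=float)       # even nm
    up_grid = np.arange(lo + 1, hi, 2, dtype=float)         # odd nm
    t = VisualPigmentTemplate(lambda_max, chromophore)
    rng = np.random.default_rng(seed)

    def noisy(grid: np.ndarray) -> SpectralCurve:
        clean = template_absorbance(t, grid).values
        eps = rng.normal(0.0, noise_sd, size=grid.size) if noise_sd > 0 else 0.0
        if ar1_rho > 0 and noise_sd > 0:
            out = np.empty(grid.size)
            prev = 0.0
            innov_sd = noise_sd * np.sqrt(1 - ar1_rho**2)
            white = rng.normal(0.0, innov_sd, size=grid.size)
            for i in range(grid.size):
                prev = ar1_rho * prev + white[i]
                out[i] = prev
            eps = out
        return SpectralCurve(grid, np.clip(clean + eps, 0.0, None))

    return interleave(noisy(down_grid), noisy(up_grid))


# ---------------------------------------------------------------------------
# Species EEMs and skin patches


def gen_species_eem(species: str) -> EEM:
    """Gaussian-mixture EEM for a species' skin/extract fluorescence.

    Components (see fixture_params.yaml) encode the measured behaviour:
    a dominant deep-UV extract band, a blue band emitting at 455 nm under
    355 nm excitation (with a 500 nm shoulder), and the green skin band
    emitting at 525-535 nm under 390/470 nm excitation.  The matrix is
    rescaled so the largest per-excitation quantum yield equals the
    configured bound.
    """
    params = fixture_params()
    if species not in params["species"]:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    g = params["eem_grids"]
    ex = np.arange(g["excitation"]["lo"], g["excitation"]["hi"] + 1,
                   g["excitation"]["step"], dtype=float)
    em = np.arange(g["emission"]["lo"], g["emission"]["hi"] + 1,
                   g["emission"]["step"], dtype=float)
    eff = np.zeros((ex.size, em.size))
    for comp in params["species"][species]["eem_components"]:
        ex_part = np.exp(-0.5 * ((ex - comp["ex_center"]) / comp["ex_sigma"]) ** 2)
        em_part = np.exp(-0.5 * ((em - comp["em_center"]) / comp["em_sigma"]) ** 2)
        eff += comp["amp"] * np.outer(ex_part, em_part)
    eff[em[None, :] <= ex[:, None]] = 0.0  # Stokes constraint
    # rescale to the configured maximum quantum yield before validation
    qmax = float(np.trapezoid(eff, em, axis=1).max())
    target = float(params["quantum_yield_max"])
    if qmax > 0:
        eff *= target / qmax
    return EEM(ex, em, eff)


def gen_patch_pair(species: str) -> tuple[SkinPatch, SkinPatch]:
    """(beige, dark) skin patches: beige is brighter and more fluorescent."""
    params = fixture_params()["patches"]
    eem = gen_species_eem(species)
    grid = np.arange(300.0, 701.0, 1.0)

    def refl(lo: float, hi: float) -> SpectralCurve:
        return SpectralCurve(grid, lo + (hi - lo) * (grid - 300.0) / 400.0)

    beige = SkinPatch(
        "beige",
        refl(params["beige"]["reflectance_lo"], params["beige"]["reflectance_hi"]),
        eem.scaled(params["beige"]["fluorescence_scale"]),
    )
    dark = SkinPatch(
        "dark",
        refl(params["dark"]["reflectance_lo"], params["dark"]["reflectance_hi"]),
        eem.scaled(params["dark"]["fluorescence_scale"]),
    )
    return beige, dark


# ---------------------------------------------------------------------------
# Phylogeny fixtures


def gen_family_tree_fixture():
    """The packaged family-level topology + fluorescent tip states.

    The fixture ships as editable data (newick + state CSV); this generator
    loads and validates it: 15 family-level tips, exactly three fluorescent.
    """
    tree, states = _origins.packaged_family_tree()
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if sorted(tips) != sorted(states):
        raise ValueError("tip labels and state table disagree")
    if sum(states.values()) != 3:
        raise ValueError("fixture must have exactly three fluorescent tips")
    return tree, states


def gen_alignment_fixture(seed: int = 0) -> dict:
    """Random nucleotide matrix with the study's partition structure.

    Three genes (ND2 1047 bp, COI 647 bp, RAG1 2475 bp; 4169 total) for the
    15 fixture families, partitioned by gene x codon position (9
    partitions). Structural only — no evolutionary model is simulated.
    Returns {"taxa": {name: sequence}, "partitions": [(label, start, end)]}
    with 0-based half-open per-gene codon-position partitions.
    """
    genes = fixture_params()["alignment"]["genes"]
    total = sum(genes.values())
    _, states = _origins.packaged_family_tree()
    taxa = sorted(states)
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    matrix = {
        t: "".join(bases[rng.integers(0, 4, size=total)]) for t in taxa
    }
    partitions = []
    offset = 0
    for gene, length in genes.items():
        for pos in (1, 2, 3):
            partitions.append((f"{gene}_pos{pos}", offset, offset + length, pos))
        offset += length
    return {"taxa": matrix, "partitions": partitions, "total_length": total}
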