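"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: parsimony by
exhaustive enumeration of internal labelings, the pigment locus by a plain
Python loop with direct trapezoidal integrals, and half-maximum crossings
by dense-grid search.
"""

from __future__ import annotations

import itertools

import numpy as np

from sharkvis.pigments import VisualPigmentTemplate, template_absorbance


def exhaustive_min_origins(tree, tip_states, ancestral_state=0):
    """(min_changes, min_gains) by enumerating all internal-state labelings."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    root = tree.seed_node
    best = (10**9, 10**9)
    for combo in itertools.product((0, 1), repeat=len(internal)):
        assign = dict(zip(internal, combo))
        if assign[root] != ancestral_state:
            continue
        changes = gains = 0
        ok = True
        for node in internal:
            s = assign[node]
            for child in node.child_nodes():
                if child.is_leaf():
                    t = int(tip_states[child.taxon.label])
                else:
                    t = assign[child]
                if s != t:
                    changes += 1
                    if s == 0:
                        gains += 1
        if (changes, gains) < best:
            best = (changes, gains)
    return best


def brute_force_locus_optimum(
    target, background, lambda_grid, chromophore="A1", rel_tol=1e-9
):
    """Optimal lambda_max by a plain loop: max |Weber|, ties by background
    catch, then lowest lambda."""
    records = []
    for lmax in np.asarray(lambda_grid, dtype=float):
        t = template_absorbance(VisualPigmentTemplate(float(lmax), chromophore))
        grid = t.wavelengths
        qt = np.trapezoid(t.values * target(grid), grid)
        qb = np.trapezoid(t.values * background(grid), grid)
        records.append((float(lmax), abs((qt - qb) / qb), qb))
    cmax = max(r[1] for r in records)
    tied = [r for r in records if r[1] >= cmax - rel_tol * max(cmax, 1e-300)]
    qmax = max(r[2] for r in tied)
    winners = [r[0] for r in tied if r[2] >= qmax - rel_tol * max(qmax, 1e-300)]
    return min(winners)


def dense_half_max(curve_fn, lo, hi, step=0.01):
    """Half-maximum crossings of a callable by dense-grid scanning."""
    grid = np.arange(lo, hi + step, step)
    v = curve_fn(grid)
    half = v.max() / 2.0
    above = np.flatnonzero(v >= half)
    return float(grid[above[0]]), float(grid[above[-1]])
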