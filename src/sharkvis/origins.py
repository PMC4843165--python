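"""Minimum evolutionary origins of a binary character on a phylogeny.

Given a rooted tree with fluorescent / non-fluorescent tip states and the
root fixed to the non-fluorescent ancestral condition, small-parsimony
dynamic programming (Sankoff) gives

* ``min_changes`` — the minimum total number of state changes, and
* ``min_gains``  — the minimum number of 0->1 transitions (independent
  origins) among all reconstructions achieving that minimum,

computed in one pass with lexicographic (changes, gains) costs, which are
additive and totally ordered so the Sankoff recursion applies unchanged.
Newick parsing is delegated to dendropy; branch lengths are accepted and
ignored (parsimony is topology-only).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import dendropy

__all__ = [
    "OriginsResult",
    "parse_newick",
    "min_origins",
    "load_tip_states",
    "packaged_family_tree",
]


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a rooted dendropy tree."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick: {exc}") from exc
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass(frozen=True)
class OriginsResult:
    """Minimum state changes and minimum gains (0->1) for the character."""

    min_changes: int
    min_gains: int

    def __post_init__(self) -> None:
        assert 0 <= self.min_gains <= self.min_changes


_INF = (10**9, 10**9)


def _pair_add(a, b):
    return (a[0] + b[0], a[1] + b[1])


def min_origins(
    tree: dendropy.Tree,
    tip_states: dict,
    ancestral_state: int = 0,
    gain_cost: int = 1,
    loss_cost: int = 1,
) -> OriginsResult:
    """Sankoff small parsimony with the root fixed to ``ancestral_state``.

    ``tip_states`` maps taxon labels to 0/1. Costs are per-change
    (``gain_cost`` for 0->1, ``loss_cost`` for 1->0); ``min_changes`` is
    the weighted parsimony score and ``min_gains`` the fewest gains among
    score-optimal reconstructions.
    """
    if ancestral_state not in (0, 1):
        raise ValueError("ancestral_state must be 0 or 1")

    # edge cost pairs: (weighted changes, gains)
    def edge_cost(parent_state: int, child_state: int):
        if parent_state == child_state:
            return (0, 0)
        if parent_state == 0:  # gain
            return (gain_cost, 1)
        return (loss_cost, 0)

    cost: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else None
            if label not in tip_states:
                raise ValueError(f"missing tip state for taxon {label!r}")
            s = int(tip_states[label])
            if s not in (0, 1):
                raise ValueError(f"tip state for {label!r} must be 0 or 1, got {s}")
            cost[node] = [(0, 0) if st == s else _INF for st in (0, 1)]
        else:
            acc = [(0, 0), (0, 0)]
            for child in node.child_nodes():
                for st in (0, 1):
                    best = min(
                        _pair_add(cost[child][t], edge_cost(st, t)) for t in (0, 1)
                    )
                    acc[st] = _pair_add(acc[st], best)
            cost[node] = acc

    changes, gains = cost[tree.seed_node][ancestral_state]
    if changes >= _INF[0]:
        raise ValueError("no feasible reconstruction (conflicting constraints)")
    return OriginsResult(int(changes), int(gains))


def load_tip_states(path) -> dict:
    """Read a `taxon,state` CSV (header optional) into a dict."""
    states: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.lower().startswith("taxon,"):
                continue
            taxon, _, state = line.rpartition(",")
            states[taxon.strip()] = int(state)
    return states


def packaged_family_tree():
    """The packaged family-level elasmobranch topology and tip states.

    Fifteen tips: the three fluorescent families (Urotrygonidae,
    Orectolobidae, Scyliorhinidae), ten examined non-fluorescent families,
    and two non-fluorescent outgroups (Chimaeridae; a bony-fish outgroup).
    Returns (tree, tip_states).
    """
    data = resources.files("sharkvis") / "data"
    tree = parse_newick((data / "elasmobranch_families.nwk").read_text())
    states: dict = {}
    for line in (data / "fluorescence_states.csv").read_text().splitlines():
        line = line.strip()
        if not line or line.lower().startswith("taxon,"):
            continue
        taxon, _, state = line.rpartition(",")
        states[taxon.strip()] = int(state)
    return tree, states
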