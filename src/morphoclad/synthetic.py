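"""Synthetic character matrices evolved on a known tree, with change logs.

The generator emulates hominoid-scale morphological data sets: 10-20
terminals, 100-200 mostly binary unordered characters, and branch-specific
change regimes including zero-rate branches (the bonobo-lineage stasis
pattern).  Change events, not per-site substitution processes, are the unit
of simulation: each branch draws a Poisson number of events per character
and each event moves the state (a flip for binary characters; for
multistate characters a uniform move, biased back toward the ancestral
state 0 by ``reversion_bias``).

The true event log is returned alongside the matrix so inference can be
scored by :func:`recovery_report`; only a branch's *net* change (start
state != end state) is observable to any method, so the log records both
the raw events and the net changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix_io import CharacterDef, CharacterMatrix
from .reconstruction import branch_name
from .trees import Node, PhyloTree, TreeError, parse_newick

__all__ = ["SyntheticSpec", "SyntheticData", "generate_matrix", "random_topology",
           "recovery_report"]


@dataclass
class SyntheticSpec:
    """Parameters of one simulation; seed fully determines the output."""

    n_taxa: int = 12
    n_characters: int = 166
    p_binary: float = 0.9
    n_states_multi: int = 3
    #: expected change events per character on each branch (Poisson mean)
    rate_per_branch: float = 0.05
    #: branch-specific overrides, keyed by child-clade branch name
    #: (e.g. "P_paniscus" or "A+B"); value 0 makes a zero-rate branch
    branch_rates: dict = field(default_factory=dict)
    #: probability that a change event on a derived state returns to state 0
    reversion_bias: float = 0.0
    seed: int = 0
    #: optional fixed topology (Newick); generated from the seed when None
    tree_newick: str = None


@dataclass
class SyntheticData:
    spec: SyntheticSpec
    tree: PhyloTree
    matrix: CharacterMatrix
    #: raw events: (char id, branch name, from state, to state) in order
    events: list
    #: net changes per branch: (char id, branch name, start state, end state)
    net_changes: list


def random_topology(labels, rng) -> PhyloTree:
    """Random rooted binary topology by sequential random attachment."""
    labels = list(labels)
    if len(labels) < 2:
        raise TreeError("need at least 2 taxa")
    root = Node(children=[Node(label=labels[0]), Node(label=labels[1])])
    for label in labels[2:]:
        edges = []

        def collect(n):
            for c in n.children:
                edges.append((n, c))
                collect(c)

        collect(root)
        parent, child = edges[rng.integers(len(edges))]
        j = parent.children.index(child)
        parent.children[j] = Node(children=[child, Node(label=label)])
    return PhyloTree(root=root).canonicalize()


def generate_matrix(spec: SyntheticSpec) -> SyntheticData:
    """Evolve a matrix on the generating tree; emit matrix, tree, event log."""
    if spec.n_taxa < 2 or spec.n_characters < 1:
        raise ValueError("need at least 2 taxa and 1 character")
    if not 0 <= spec.p_binary <= 1:
        raise ValueError("p_binary must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    labels = [f"T{i + 1:02d}" for i in range(spec.n_taxa)]
    if spec.tree_newick is not None:
        tree = parse_newick(spec.tree_newick)
        if sorted(tree.leaf_labels()) != sorted(labels):
            labels = tree.leaf_labels()
    else:
        tree = random_topology(labels, rng)
    clades = tree.clades()

    characters = []
    for i in range(spec.n_characters):
        binary = rng.random() < spec.p_binary
        n_states = 2 if binary else spec.n_states_multi
        characters.append(
            CharacterDef(
                id=i + 1,
                label=f"synthetic character {i + 1}",
                state_labels=tuple(str(s) for s in range(n_states)),
                kind="major" if rng.random() < 0.5 else "minor",
                region=("HN", "FL", "HL", "trunk")[rng.integers(4)],
            )
        )

    def branch_rate(clade) -> float:
        return float(spec.branch_rates.get(branch_name(clade), spec.rate_per_branch))

    events, net_changes = [], []
    tip_states = {c.id: {} for c in characters}
    for char in characters:
        n_states = char.n_states
        states = {id(tree.root): 0}
        for parent, child in tree.edges():
            state = states[id(parent)]
            start = state
            k = rng.poisson(branch_rate(clades[child]))
            for _ in range(k):
                if n_states == 2:
                    new = 1 - state
                elif state != 0 and rng.random() < spec.reversion_bias:
                    new = 0
                else:
                    choices = [s for s in range(n_states) if s != state]
                    new = choices[rng.integers(len(choices))]
                events.append((char.id, branch_name(clades[child]), state, new))
                state = new
            states[id(child)] = state
            if state != start:
                net_changes.append(
                    (char.id, branch_name(clades[child]), start, state)
                )
        for leaf in tree.leaves():
            tip_states[char.id][leaf.label] = states[id(leaf)]

    rows = {
        t: tuple(frozenset([tip_states[c.id][t]]) for c in characters)
        for t in labels
    }
    matrix = CharacterMatrix(taxa=list(labels), characters=characters, rows=rows)
    return SyntheticData(
        spec=spec, tree=tree, matrix=matrix, events=events, net_changes=net_changes
    )


def recovery_report(data: SyntheticData, change_map) -> dict:
    """Precision/recall of inferred against true net changes, per branch.

    Matching is exact on (character id, branch name) for the inferred
    records (unambiguous ones are additionally reported separately).
    Raises if the inferred map references branches outside the generating
    tree.
    """
    true_keys = {(cid, branch) for cid, branch, _, _ in data.net_changes}
    clades = data.tree.clades()
    tree_branches = {branch_name(clades[child]) for _, child in data.tree.edges()}
    inferred_all, inferred_unambiguous = set(), set()
    for r in change_map.records:
        key = (r.char_id, r.branch)
        if r.branch not in tree_branches:
            raise ValueError(f"inferred change on unknown branch {r.branch!r}")
        inferred_all.add(key)
        if r.ambiguous is False:
            inferred_unambiguous.add(key)

    def prf(inferred):
        tp = len(inferred & true_keys)
        precision = tp / len(inferred) if inferred else 1.0
        recall = tp / len(true_keys) if true_keys else 1.0
        return {"true": len(true_keys), "inferred": len(inferred), "matched": tp,
                "precision": precision, "recall": recall}

    per_branch = {}
    for b in tree_branches:
        t = {k for k in true_keys if k[1] == b}
        i = {k for k in inferred_all if k[1] == b}
        tp = len(t & i)
        per_branch[b] = {
            "true": len(t),
            "inferred": len(i),
            "matched": tp,
            "precision": tp / len(i) if i else 1.0,
            "recall": tp / len(t) if t else 1.0,
        }
    return {
        "overall": prf(inferred_all),
        "unambiguous": prf(inferred_unambiguous),
        "per_branch": per_branch,
    }
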