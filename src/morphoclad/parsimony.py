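"""Unordered (Fitch) parsimony: tree lengths, homoplasy indices, tree search.

Scoring uses the unit-cost small-phylogeny dynamic programme (Sankoff with a
uniform substitution cost), which coincides with Fitch counting on binary
trees and remains exact on polytomies.  MISSING and INAPPLICABLE tips carry
the full state domain and can never force a step.

The ensemble consistency index CI = sum(m_i)/sum(s_i) and retention index
RI = (sum(g_i) - sum(s_i)) / (sum(g_i) - sum(m_i)) follow the standard
definitions, with m_i the minimum steps any tree needs for character i and
g_i the steps on a star tree (the maximum any tree can need).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .matrix_io import CharacterMatrix
from .trees import Node, PhyloTree, TreeError, enumerate_topologies

__all__ = [
    "TreeScore",
    "fitch_length",
    "per_character_steps",
    "char_min_steps",
    "char_max_steps",
    "ensemble_indices",
    "branch_and_bound_search",
]

_INF = np.float64(1e9)


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class TreeScore:
    """Parsimony score of one tree against one matrix."""

    length: int
    per_character_steps: dict  # char id -> steps
    ci: float  # 0..1, full precision
    ri: float
    ci_percent: int  # rounded, half away from zero
    ri_percent: int
    ci_includes_uninformative: bool = True
    undefined_ci: bool = False  # L == 0

    def as_dict(self) -> dict:
        return {
            "length": self.length,
            "per_character_steps": {str(k): v for k, v in self.per_character_steps.items()},
            "ci": self.ci,
            "ri": self.ri,
            "ci_percent": self.ci_percent,
            "ri_percent": self.ri_percent,
            "ci_includes_uninformative": self.ci_includes_uninformative,
            "undefined_ci": self.undefined_ci,
        }


# -- single-character scoring ---------------------------------------------


def _state_sets_for_tree(tree: PhyloTree, state_sets: dict):
    leaves = tree.leaf_labels()
    missing = [l for l in leaves if l not in state_sets]
    if missing:
        raise TreeError(f"terminals absent from matrix: {missing}")
    return [state_sets[l] for l in leaves]


def _min_cost(tree: PhyloTree, tip_sets: dict, n_states: int) -> np.ndarray:
    """Root cost vector of the unit-cost DP; tip_sets maps leaf label -> set."""
    costs = {}
    for node in tree.postorder():
        if node.is_leaf():
            vec = np.full(n_states, _INF)
            for s in tip_sets[node.label]:
                vec[s] = 0.0
            costs[id(node)] = vec
        else:
            total = np.zeros(n_states)
            for child in node.children:
                cvec = costs[id(child)]
                best = cvec.min()
                # cost of state s at parent via this child: min(c[s], best+1)
                total += np.minimum(cvec, best + 1.0)
            costs[id(node)] = total
    return costs[id(tree.root)]


def fitch_length(tree: PhyloTree, matrix: CharacterMatrix, char_id: int) -> int:
    """Minimum number of unordered state changes for one character."""
    char = matrix.char_by_id(char_id)
    sets = matrix.state_sets(char_id)
    _state_sets_for_tree(tree, sets)
    root = _min_cost(tree, sets, char.n_states)
    best = root.min()
    if best >= _INF:
        raise ValueError(f"character {char_id} has an empty feasible state set")
    return int(best)


def per_character_steps(tree: PhyloTree, matrix: CharacterMatrix) -> dict:
    """Steps s_i for every character on the tree (one DP per character)."""
    return {c.id: fitch_length(tree, matrix, c.id) for c in matrix.characters}


# -- per-character bounds ---------------------------------------------------


def char_min_steps(matrix: CharacterMatrix, char_id: int) -> int:
    """m_i: fewest steps any tree can need.

    Computed as (size of a minimum hitting set of the scorable tip state
    sets) - 1: some state must be pickable for every tip, and k states
    observed across tips force at least k-1 changes somewhere.  Equals
    (number of distinct observed states) - 1 when no tip is polymorphic.
    """
    sets = [s for s in matrix.scorable_sets(char_id).values()]
    if not sets:
        return 0
    domain = sorted(set().union(*sets))
    for k in range(1, len(domain) + 1):
        for combo in itertools.combinations(domain, k):
            chosen = set(combo)
            if all(chosen & s for s in sets):
                return k - 1
    return len(domain) - 1  # unreachable: full domain always hits


def char_max_steps(matrix: CharacterMatrix, char_id: int) -> int:
    """g_i: steps on a star tree = n_scorable - max state coverage.

    Polymorphic tips count toward whichever state serves them best.
    """
    sets = list(matrix.scorable_sets(char_id).values())
    if not sets:
        return 0
    domain = set().union(*sets)
    best = max(sum(1 for s in sets if st in s) for st in domain)
    return len(sets) - best


# -- ensemble indices -------------------------------------------------------


def ensemble_indices(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    include_uninformative: bool = True,
) -> TreeScore:
    """Tree length with ensemble CI and RI.

    ``include_uninformative`` controls whether characters with g_i == m_i
    (parsimony-uninformative) enter the CI sums (the PAUP default includes
    them); such characters never affect RI, whose 0/0 terms are excluded.
    """
    steps = per_character_steps(tree, matrix)
    L = sum(steps.values())
    sum_m = sum_s = 0
    sum_g_ri = sum_m_ri = sum_s_ri = 0
    for c in matrix.characters:
        m = char_min_steps(matrix, c.id)
        g = char_max_steps(matrix, c.id)
        s = steps[c.id]
        informative = g > m
        if include_uninformative or informative:
            sum_m += m
            sum_s += s
        if informative:
            sum_g_ri += g
            sum_m_ri += m
            sum_s_ri += s
    undefined_ci = sum_s == 0
    ci = 1.0 if undefined_ci else sum_m / sum_s
    ri = 1.0 if sum_g_ri == sum_m_ri else (sum_g_ri - sum_s_ri) / (sum_g_ri - sum_m_ri)
    return TreeScore(
        length=L,
        per_character_steps=steps,
        ci=ci,
        ri=ri,
        ci_percent=_round_half_up(100 * ci),
        ri_percent=_round_half_up(100 * ri),
        ci_includes_uninformative=include_uninformative,
        undefined_ci=undefined_ci,
    )


# -- search -----------------------------------------------------------------


def _pack_columns(matrix: CharacterMatrix) -> dict:
    """Per-taxon tip cost arrays (n_characters x max_states), INF-padded.

    Lets one postorder sweep score every character at once, which is what
    makes exact search over many characters practical.
    """
    from .matrix_io import _Sentinel

    n_chars = len(matrix.characters)
    S = max((c.n_states for c in matrix.characters), default=1)
    tip_costs = {}
    for t in matrix.taxa:
        arr = np.full((n_chars, S), _INF)
        for j, c in enumerate(matrix.characters):
            cell = matrix.rows[t][j]
            states = range(c.n_states) if isinstance(cell, _Sentinel) else cell
            for s in states:
                arr[j, s] = 0.0
        tip_costs[t] = arr
    return tip_costs


def _tree_length(tree: PhyloTree, tip_costs: dict) -> int:
    """Total steps over all characters in one vectorized postorder sweep."""

    def walk(node):
        if node.is_leaf():
            return tip_costs[node.label]
        total = None
        for child in node.children:
            cvec = walk(child)
            m = np.minimum(cvec, cvec.min(axis=1, keepdims=True) + 1.0)
            total = m if total is None else total + m
        return total

    return int(walk(tree.root).min(axis=1).sum())


def branch_and_bound_search(
    matrix: CharacterMatrix,
    outgroup: str,
    max_taxa: int = 16,
):
    """All minimum-length unrooted topologies, rooted on the outgroup.

    Exact search by stepwise taxon addition with an incumbent-length bound:
    parsimony length never decreases when a taxon is added, so any partial
    tree longer than the best complete tree can be discarded.  Returns
    ``(trees, score)`` where ``trees`` are canonical :class:`PhyloTree`
    objects and ``score`` is the :class:`TreeScore` of the optimum.
    """
    taxa = list(matrix.taxa)
    if outgroup not in taxa:
        raise TreeError(f"outgroup {outgroup!r} is not in the matrix")
    if len(taxa) < 3:
        raise TreeError("search needs at least 3 taxa")
    if len(taxa) > max_taxa:
        raise TreeError(
            f"{len(taxa)} taxa exceed the exact-search ceiling of {max_taxa}; "
            "a heuristic search is out of scope"
        )
    tip_costs = _pack_columns(matrix)
    others = [t for t in taxa if t != outgroup]
    # addition order: as given; the unrooted tree is represented rooted with
    # the outgroup as first child of the root (bijection with unrooted trees)
    first_three = [outgroup] + others[:2]
    rest = others[2:]

    def make_initial():
        a, b, c = first_three
        return Node(children=[Node(label=a), Node(children=[Node(label=b), Node(label=c)])])

    def attachments(root):
        """Each unrooted edge exactly once, in the rooted representation.

        The rooted edges root->outgroup and root->rest are the same unrooted
        edge, so the one above the outgroup leaf is skipped.
        """
        edges = []

        def collect(n):
            for ch in n.children:
                if not (n is root and ch.is_leaf() and ch.label == outgroup):
                    edges.append((n, ch))
                collect(ch)

        collect(root)
        return edges

    best = {"length": None, "trees": []}

    def length_of(root) -> int:
        sub = {l: tip_costs[l] for l in PhyloTree(root=root).leaf_labels()}
        return _tree_length(PhyloTree(root=root), sub)

    def recurse(root, remaining):
        partial = length_of(root)
        if best["length"] is not None and partial > best["length"]:
            return
        if not remaining:
            key_tree = PhyloTree(root=root.copy(), outgroup=outgroup).canonicalize()
            if best["length"] is None or partial < best["length"]:
                best["length"] = partial
                best["trees"] = [key_tree]
            elif partial == best["length"]:
                key = key_tree.topology_key()
                if key not in {t.topology_key() for t in best["trees"]}:
                    best["trees"].append(key_tree)
            return
        label, rest2 = remaining[0], remaining[1:]
        edges = attachments(root)
        for idx in range(len(edges)):
            fresh = root.copy()
            parent, child = attachments(fresh)[idx]
            j = parent.children.index(child)
            parent.children[j] = Node(children=[child, Node(label=label)])
            recurse(fresh, rest2)

    recurse(make_initial(), rest)
    trees = sorted(best["trees"], key=lambda t: str(t.topology_key()))
    score = ensemble_indices(trees[0], matrix)
    return trees, score


def exhaustive_search(matrix: CharacterMatrix, outgroup: str):
    """Reference search scoring every unrooted topology (n <= 9 guard).

    Oracle counterpart of :func:`branch_and_bound_search`; kept in the
    library so tests and the CLI can cross-check the pruned search.
    """
    taxa = [outgroup] + [t for t in matrix.taxa if t != outgroup]
    tip_costs = _pack_columns(matrix)
    best_len, best_trees = None, []
    for tree in enumerate_topologies(taxa, rooted=False):
        L = _tree_length(tree, tip_costs)
        if best_len is None or L < best_len:
            best_len, best_trees = L, [tree]
        elif L == best_len:
            best_trees.append(tree)
    trees = []
    for t in best_trees:
        t.outgroup = outgroup
        trees.append(t.canonicalize())
    trees.sort(key=lambda t: str(t.topology_key()))
    score = ensemble_indices(trees[0], matrix)
    return trees, score
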