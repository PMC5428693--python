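"""Most-parsimonious reconstructions (MPRs) and branch change maps.

For each character all minimum-change assignments of states to nodes are
enumerated by backtracking over the parsimony dynamic programme.  Changes
are mapped to branches, classified as acquisitions (away from the root
state) or reversions (back to the root state), and flagged unambiguous when
the same branch/from/to change occurs in every MPR.

Where the MPR set is ambiguous, a single reconstruction is selected for
reporting by the ACCTRAN/DELTRAN conventions: DELTRAN delays transformations
(changes as close to the tips as possible, favouring independent terminal
gains), ACCTRAN accelerates them (early gain, later reversals).  Selection
operates on the full MPR set by total root-to-change depth, so both
conventions always pick a genuine MPR.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .matrix_io import CharacterMatrix
from .trees import PhyloTree, TreeError

__all__ = [
    "ChangeRecord",
    "Reconstruction",
    "ChangeMap",
    "enumerate_mprs",
    "select_reconstruction",
    "map_branch_changes",
    "classify_changes",
    "summarize_synapomorphies",
    "branch_name",
]

_INF = 1e9


def branch_name(clade: frozenset) -> str:
    """Readable branch id: the subtended leaf set joined with '+'."""
    return "+".join(sorted(clade))


@dataclass(frozen=True)
class ChangeRecord:
    """One inferred state transition on a branch."""

    char_id: int
    parent_clade: frozenset
    child_clade: frozenset
    from_state: int
    to_state: int
    direction: str = None  # "acquisition" | "reversion"
    ambiguous: bool = None  # vs. the full MPR set

    @property
    def branch(self) -> str:
        return branch_name(self.child_clade)

    @property
    def key(self):
        """Identity of the change across MPRs: branch + states."""
        return (self.char_id, self.child_clade, self.from_state, self.to_state)


@dataclass
class Reconstruction:
    """One full most-parsimonious assignment of states for one character."""

    char_id: int
    node_states: dict  # clade frozenset -> state (terminals included)
    changes: list
    root_state: int

    @property
    def total_changes(self) -> int:
        return len(self.changes)

    def state_vector(self):
        return tuple(sorted(((branch_name(c), s) for c, s in self.node_states.items())))


@dataclass
class ChangeMap:
    """Per-branch changes for a whole matrix under one reporting policy."""

    policy: str
    records: list = field(default_factory=list)  # classified ChangeRecords
    reconstructions: dict = field(default_factory=dict)  # char id -> selected MPR
    mpr_counts: dict = field(default_factory=dict)  # char id -> number of MPRs

    def by_branch(self) -> dict:
        out = {}
        for r in self.records:
            out.setdefault(r.child_clade, []).append(r)
        return out

    def branch_records(self, clade: frozenset) -> list:
        return [r for r in self.records if r.child_clade == clade]

    def clade_records(self, clade: frozenset, include_stem: bool = True) -> list:
        """Changes inside a clade (stem branch included by default)."""
        out = []
        for r in self.records:
            if r.child_clade < clade or (include_stem and r.child_clade == clade):
                out.append(r)
        return out


# -- MPR enumeration --------------------------------------------------------


def _dp_costs(tree: PhyloTree, tip_sets: dict, n_states: int) -> dict:
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
                total += np.minimum(cvec, cvec.min() + 1.0)
            costs[id(node)] = total
    return costs


def enumerate_mprs(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    char_id: int,
    max_mprs: int = 100000,
) -> list:
    """Every distinct minimum-change state assignment for one character.

    Terminals with polymorphic or missing cells are fixed to one element of
    their state set per reconstruction, so wildcard tips multiply the MPR
    set.  Each reconstruction carries its branch changes; their number
    always equals the character's minimum length.
    """
    char = matrix.char_by_id(char_id)
    tip_sets = matrix.state_sets(char_id)
    missing = [l for l in tree.leaf_labels() if l not in tip_sets]
    if missing:
        raise TreeError(f"terminals absent from matrix: {missing}")
    n_states = char.n_states
    costs = _dp_costs(tree, tip_sets, n_states)
    clades = tree.clades()

    root_vec = costs[id(tree.root)]
    best = root_vec.min()
    root_choices = [s for s in range(n_states) if root_vec[s] == best]

    def options(node, parent_state):
        vec = costs[id(node)]
        with_parent = vec + (np.arange(n_states) != parent_state)
        target = with_parent.min()
        return [s for s in range(n_states) if with_parent[s] == target]

    results = []

    def assign(node, state, assignment):
        assignment = dict(assignment)
        assignment[clades[node]] = state
        if node.is_leaf():
            yield assignment
            return
        child_opts = [options(c, state) for c in node.children]
        for combo in itertools.product(*child_opts):
            partials = [assignment]
            for c, cs in zip(node.children, combo):
                nxt = []
                for p in partials:
                    for a in assign(c, cs, p):
                        nxt.append(a)
                partials = nxt
            yield from partials

    for root_state in root_choices:
        for assignment in assign(tree.root, root_state, {}):
            changes = []
            for parent, child in tree.edges():
                fs = assignment[clades[parent]]
                ts = assignment[clades[child]]
                if fs != ts:
                    changes.append(
                        ChangeRecord(
                            char_id=char_id,
                            parent_clade=clades[parent],
                            child_clade=clades[child],
                            from_state=fs,
                            to_state=ts,
                        )
                    )
            results.append(
                Reconstruction(
                    char_id=char_id,
                    node_states=assignment,
                    changes=changes,
                    root_state=root_state,
                )
            )
            if len(results) > max_mprs:
                raise RuntimeError(
                    f"more than {max_mprs} MPRs for character {char_id}"
                )
    # deduplicate by full node-state vector (distinct by construction, but
    # keep the contract explicit)
    seen, unique = set(), []
    for r in results:
        v = r.state_vector()
        if v not in seen:
            seen.add(v)
            unique.append(r)
    return unique


# -- policy selection and classification ------------------------------------


def select_reconstruction(tree: PhyloTree, mprs: list, policy: str = "deltran"):
    """Pick one MPR by the DELTRAN or ACCTRAN convention.

    Candidates are filtered in preorder: at each node DELTRAN keeps the MPRs
    that inherit the parent's state whenever any candidate does (delaying
    transformations toward the tips), while ACCTRAN keeps the MPRs that
    change state on the branch whenever any candidate does (accelerating
    transformations toward the root).  Filtering within the MPR set
    guarantees the selected reconstruction attains the minimum length;
    remaining ties break on the sorted node-state vector.
    """
    if policy not in ("deltran", "acctran"):
        raise ValueError(f"unknown policy {policy!r}")
    prefer_change = policy == "acctran"
    clades = tree.clades()
    parents = {id(c): p for p, c in tree.edges()}
    candidates = list(mprs)
    for node in tree.preorder():
        if node is tree.root or len(candidates) == 1:
            continue
        parent = parents[id(node)]
        pc, cc = clades[parent], clades[node]
        changed = [r for r in candidates if r.node_states[pc] != r.node_states[cc]]
        same = [r for r in candidates if r.node_states[pc] == r.node_states[cc]]
        if prefer_change and changed:
            candidates = changed
        elif not prefer_change and same:
            candidates = same
    return min(candidates, key=lambda r: r.state_vector())


def classify_changes(records, reconstruction: Reconstruction) -> list:
    """Label each change acquisition or reversion against the root state.

    A change is a reversion iff it returns to the reconstruction's root
    (ancestral) state from a non-root state; every other change moves away
    from the ancestral condition and is an acquisition.
    """
    root = reconstruction.root_state
    out = []
    for r in records:
        direction = (
            "reversion" if (r.to_state == root and r.from_state != root) else "acquisition"
        )
        out.append(replace(r, direction=direction))
    return out


def map_branch_changes(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    policy: str = "deltran",
) -> ChangeMap:
    """Branch changes for every character under one reporting policy.

    Ambiguity flags come from the full MPR set: a record is unambiguous iff
    the identical branch/from/to change occurs in every MPR of its
    character.
    """
    cmap = ChangeMap(policy=policy)
    for c in matrix.characters:
        mprs = enumerate_mprs(tree, matrix, c.id)
        cmap.mpr_counts[c.id] = len(mprs)
        common = set.intersection(*(set(r.key for r in m.changes) for m in mprs))
        chosen = select_reconstruction(tree, mprs, policy=policy)
        cmap.reconstructions[c.id] = chosen
        records = [replace(r, ambiguous=r.key not in common) for r in chosen.changes]
        cmap.records.extend(classify_changes(records, chosen))
    return cmap


# -- synapomorphy table ------------------------------------------------------


def summarize_synapomorphies(tree: PhyloTree, matrix: CharacterMatrix) -> dict:
    """Per-node table of unambiguous changes and ambiguous candidates.

    Returns {child clade: {"unambiguous": [ChangeRecord, ...],
    "ambiguous": [{"char_id": id, "placements": [ChangeRecord, ...]}, ...]}}
    where a node's entry describes the branch subtending it.  An ambiguous
    candidate lists, for each character, every alternative placement of its
    non-universal changes across the MPR set.
    """
    clades = tree.clades()
    table = {
        clade: {"unambiguous": [], "ambiguous": []}
        for node, clade in clades.items()
        if node is not tree.root
    }
    for c in matrix.characters:
        mprs = enumerate_mprs(tree, matrix, c.id)
        all_keys = [set(r.key for r in m.changes) for m in mprs]
        common = set.intersection(*all_keys)
        every = {}
        for m in mprs:
            for r in classify_changes(m.changes, m):
                every.setdefault(r.key, r)
        for key, record in every.items():
            if key in common:
                table[record.child_clade]["unambiguous"].append(record)
        ambiguous_keys = [k for k in every if k not in common]
        touched = {every[k].child_clade for k in ambiguous_keys}
        for clade in touched:
            table[clade]["ambiguous"].append(
                {
                    "char_id": c.id,
                    "placements": [every[k] for k in ambiguous_keys],
                }
            )
    return table
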