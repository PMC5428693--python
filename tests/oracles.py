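"""Independent brute-force oracles for parsimony quantities.

These deliberately share no code with the library's dynamic programmes:
they enumerate every explicit assignment of states to nodes (wildcard and
polymorphic tips included) and count differing branch endpoints directly.
Only usable on small trees.
"""

import itertools

from morphoclad.matrix_io import _Sentinel


def _tip_choices(tree, matrix, char_id):
    char = matrix.char_by_id(char_id)
    domain = list(range(char.n_states))
    choices = []
    leaves = tree.leaves()
    for leaf in leaves:
        cell = matrix.cell(leaf.label, char_id)
        choices.append(domain if isinstance(cell, _Sentinel) else sorted(cell))
    return leaves, choices, domain


def brute_force_assignments(tree, matrix, char_id):
    """Yield (node_states dict keyed by clade, n_changes) for every explicit
    assignment of tip and internal states."""
    leaves, tip_choices, domain = _tip_choices(tree, matrix, char_id)
    clades = tree.clades()
    internals = [n for n in tree.postorder() if not n.is_leaf()]
    edges = list(tree.edges())
    for tip_combo in itertools.product(*tip_choices):
        fixed = {clades[l]: s for l, s in zip(leaves, tip_combo)}
        for internal_combo in itertools.product(domain, repeat=len(internals)):
            states = dict(fixed)
            for node, s in zip(internals, internal_combo):
                states[clades[node]] = s
            n = sum(
                1
                for p, c in edges
                if states[clades[p]] != states[clades[c]]
            )
            yield states, n


def brute_force_min_length(tree, matrix, char_id):
    return min(n for _, n in brute_force_assignments(tree, matrix, char_id))


def brute_force_mprs(tree, matrix, char_id):
    """Set of optimal assignments as sorted (branch-name, state) tuples."""
    from morphoclad.reconstruction import branch_name

    assignments = list(brute_force_assignments(tree, matrix, char_id))
    best = min(n for _, n in assignments)
    out = set()
    for states, n in assignments:
        if n == best:
            out.add(tuple(sorted((branch_name(c), s) for c, s in states.items())))
    return best, out


def star_tree_length(matrix, char_id):
    """Brute-force minimum changes on a star tree (one internal node)."""
    char = matrix.char_by_id(char_id)
    sets = list(matrix.scorable_sets(char_id).values())
    if not sets:
        return 0
    best = None
    for center in range(char.n_states):
        n = sum(1 for s in sets if center not in s)
        best = n if best is None else min(best, n)
    return best
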