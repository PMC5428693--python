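"""Rooted trees over terminal taxa: Newick I/O, rerooting, enumeration.

The internal representation is a rooted tree of :class:`Node` objects whose
internal nodes normally have two children (polytomies are accepted on input
and flagged; parsimony scoring handles them, topology search does not emit
them).  Node ages, when present, are in Ma before present and live on nodes;
branch spans are parent age minus child age.

Serialization is canonical: children are ordered by their lexicographically
smallest descendant label, so equal topologies serialize identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = [
    "Node",
    "PhyloTree",
    "TreeError",
    "parse_newick",
    "write_newick",
    "enumerate_topologies",
    "reroot",
    "n_unrooted_topologies",
    "n_rooted_topologies",
]


class TreeError(ValueError):
    """Malformed Newick or invalid tree operation."""


@dataclass(eq=False)
class Node:
    label: str = None
    children: list = field(default_factory=list)
    age: float = None

    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(
            label=self.label,
            children=[c.copy() for c in self.children],
            age=self.age,
        )


@dataclass
class PhyloTree:
    """A rooted tree; ``outgroup`` names the terminal used for rooting."""

    root: Node
    outgroup: str = None

    # -- traversal ---------------------------------------------------------

    def postorder(self):
        def walk(node):
            for c in node.children:
                yield from walk(c)
            yield node

        yield from walk(self.root)

    def preorder(self):
        def walk(node):
            yield node
            for c in node.children:
                yield from walk(c)

        yield from walk(self.root)

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_labels(self) -> list:
        return [n.label for n in self.leaves()]

    def edges(self):
        """(parent, child) pairs in preorder."""
        for node in self.preorder():
            for c in node.children:
                yield node, c

    def clade(self, node: Node) -> frozenset:
        if node.is_leaf():
            return frozenset([node.label])
        return frozenset(l.label for l in PhyloTree(node).leaves())

    def clades(self) -> dict:
        """node -> frozenset of descendant leaf labels, for the whole tree."""
        out = {}
        for node in self.postorder():
            if node.is_leaf():
                out[node] = frozenset([node.label])
            else:
                out[node] = frozenset().union(*(out[c] for c in node.children))
        return out

    def find_clade_node(self, clade: frozenset) -> Node:
        for node, cl in self.clades().items():
            if cl == clade:
                return node
        raise KeyError(f"no node subtending {sorted(clade)}")

    def has_polytomy(self) -> bool:
        return any(len(n.children) > 2 for n in self.postorder())

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    # -- canonical form ----------------------------------------------------

    def canonicalize(self) -> "PhyloTree":
        """Sort children in place by smallest descendant label; return self."""

        def walk(node) -> str:
            if node.is_leaf():
                return node.label
            keys = [walk(c) for c in node.children]
            order = sorted(range(len(keys)), key=lambda i: keys[i])
            node.children = [node.children[i] for i in order]
            return min(keys)

        walk(self.root)
        return self

    def copy(self) -> "PhyloTree":
        return PhyloTree(root=self.root.copy(), outgroup=self.outgroup)

    def topology_key(self):
        """Hashable canonical topology (ignores ages)."""

        def walk(node):
            if node.is_leaf():
                return node.label
            return tuple(sorted((walk(c) for c in node.children), key=str))

        return walk(self.root)

    # -- ages --------------------------------------------------------------

    def set_ages(self, ages: dict) -> "PhyloTree":
        """Assign node ages from {clade frozenset or leaf label: age in Ma}.

        Leaves default to age 0.  Raises if a parent ends up younger than a
        child.
        """
        clades = self.clades()
        for node, clade in clades.items():
            if node.is_leaf():
                node.age = float(ages.get(node.label, ages.get(clade, 0.0)))
            else:
                if clade not in ages:
                    raise TreeError(f"no age supplied for clade {sorted(clade)}")
                node.age = float(ages[clade])
        for parent, child in self.edges():
            if parent.age < child.age:
                raise TreeError(
                    f"parent age {parent.age} < child age {child.age} at clade "
                    f"{sorted(clades[child])}"
                )
        return self

    def branch_span(self, parent: Node, child: Node) -> float:
        if parent.age is None or child.age is None:
            raise TreeError("branch span requested on a tree without ages")
        return parent.age - child.age


# -- Newick ----------------------------------------------------------------


def parse_newick(text: str, outgroup: str = None) -> PhyloTree:
    """Parse Newick text into a :class:`PhyloTree`.

    Polytomies are retained.  If every edge carries a length and the tree is
    ultrametric, node ages are reconstructed as heights above the leaves.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeError(f"Newick parse failed: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise TreeError("unlabeled terminal in Newick input")
            return Node(label=dnode.taxon.label.replace(" ", "_"))
        return Node(children=[convert(c) for c in dnode.child_nodes()])

    root = convert(dtree.seed_node)
    tree = PhyloTree(root=root, outgroup=outgroup)
    labels = tree.leaf_labels()
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate terminal labels in Newick input")
    if outgroup is not None and outgroup not in labels:
        raise TreeError(f"outgroup {outgroup!r} is not a terminal of the tree")

    # recover ages from branch lengths when the tree is ultrametric
    dnodes = [n for n in dtree.postorder_node_iter()]
    if all(n.edge.length is not None for n in dnodes if n.parent_node is not None):
        heights = {}
        ok = True
        for dnode in dtree.postorder_node_iter():
            if dnode.is_leaf():
                heights[dnode] = 0.0
            else:
                hs = [heights[c] + c.edge.length for c in dnode.child_nodes()]
                if max(hs) - min(hs) > 1e-9 * max(1.0, max(hs)):
                    ok = False
                    break
                heights[dnode] = hs[0]
        if ok:
            def assign(dnode, node):
                node.age = heights[dnode]
                for dc, c in zip(dnode.child_nodes(), node.children):
                    assign(dc, c)

            assign(dtree.seed_node, root)
    return tree.canonicalize()


def write_newick(tree: PhyloTree) -> str:
    """Canonical Newick text; ages (if present everywhere) become branch lengths."""
    tree = tree.copy().canonicalize()
    with_ages = all(n.age is not None for n in tree.postorder())

    def fmt(node, parent) -> str:
        if node.is_leaf():
            text = node.label
        else:
            text = "(" + ",".join(fmt(c, node) for c in node.children) + ")"
        if with_ages and parent is not None:
            text += f":{parent.age - node.age:g}"
        return text

    return fmt(tree.root, None) + ";"


# -- enumeration and rerooting --------------------------------------------


def _double_factorial(k: int) -> int:
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


def n_rooted_topologies(n: int) -> int:
    """(2n-3)!! rooted binary topologies on n labeled terminals."""
    return 1 if n < 2 else _double_factorial(2 * n - 3)


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! unrooted binary topologies on n labeled terminals."""
    return 1 if n < 3 else _double_factorial(2 * n - 5)


def _enumerate_rooted(labels):
    """Yield every rooted binary topology over the labels, each exactly once."""
    labels = list(labels)
    if len(labels) == 1:
        yield Node(label=labels[0])
        return

    def count_edges(node):
        edges = []

        def collect(n):
            for c in n.children:
                edges.append((n, c))
                collect(c)

        collect(node)
        return edges

    def insertions(node, leaf_label):
        """Yield copies of the tree with the new leaf attached on each edge
        and above the root — the (2k-3) insertion points of rooted trees."""
        yield Node(children=[node.copy(), Node(label=leaf_label)])
        for idx in range(len(count_edges(node))):
            fresh = node.copy()
            parent, child = count_edges(fresh)[idx]
            j = parent.children.index(child)
            parent.children[j] = Node(children=[child, Node(label=leaf_label)])
            yield fresh

    trees = [Node(label=labels[0])]
    for label in labels[1:]:
        nxt = []
        for t in trees:
            nxt.extend(insertions(t, label))
        trees = nxt
    yield from trees


def enumerate_topologies(taxa, rooted: bool = True):
    """Yield every distinct topology over the taxa exactly once.

    Unrooted topologies are represented rooted at the first taxon (the first
    taxon becomes one child of an artificial root), the standard bijection
    between unrooted n-taxon and rooted (n-1)-taxon trees.  Guarded to
    2 <= n <= 9.
    """
    taxa = list(taxa)
    n = len(taxa)
    if not 2 <= n <= 9:
        raise TreeError(f"topology enumeration supports 2..9 taxa, got {n}")
    if rooted:
        for root in _enumerate_rooted(taxa):
            yield PhyloTree(root=root).canonicalize()
    else:
        first, rest = taxa[0], taxa[1:]
        if not rest:
            yield PhyloTree(root=Node(label=first)).canonicalize()
            return
        for sub in _enumerate_rooted(rest):
            root = Node(children=[Node(label=first), sub])
            yield PhyloTree(root=root, outgroup=first).canonicalize()


def reroot(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root the (unrooted-equivalent) tree on the branch subtending `outgroup`.

    Node ages are dropped: they are meaningful only for a fixed rooting.
    """
    labels = tree.leaf_labels()
    if outgroup not in labels:
        raise TreeError(f"unknown outgroup label {outgroup!r}")

    # build undirected adjacency, suppressing a degree-2 root
    tree = tree.copy()
    adj = {}

    def add(a, b):
        adj.setdefault(id(a), []).append(b)
        adj.setdefault(id(b), []).append(a)

    nodes = {id(n): n for n in tree.postorder()}
    for parent, child in tree.edges():
        add(parent, child)
    root = tree.root
    if len(root.children) == 2:
        a, b = root.children
        adj[id(a)] = [x for x in adj[id(a)] if x is not root] + [b]
        adj[id(b)] = [x for x in adj[id(b)] if x is not root] + [a]
        del adj[id(root)]

    out_leaf = next(n for n in nodes.values() if n.is_leaf() and n.label == outgroup)

    def build(node, come_from) -> Node:
        neighbors = [x for x in adj[id(node)] if x is not come_from]
        if not neighbors:
            return Node(label=node.label)
        return Node(children=[build(x, node) for x in neighbors])

    neighbor = adj[id(out_leaf)][0]
    new_root = Node(children=[Node(label=outgroup), build(neighbor, out_leaf)])
    return PhyloTree(root=new_root, outgroup=outgroup).canonicalize()
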