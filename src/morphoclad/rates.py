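"""Pairwise character differences and calibrated divergence rates.

A difference between two taxa is counted only when their coded state sets
are disjoint: a polymorphic taxon that overlaps the other taxon's states is
not a consistent difference.  Rates are plain changes-per-Ma quotients;
display rounding follows the field's convention of two decimals below 1 and
one decimal at or above 1 (0.28, 0.5, 3.5), while stored values keep full
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .matrix_io import CharacterMatrix, _Sentinel
from .reconstruction import branch_name
from .trees import PhyloTree, TreeError

__all__ = [
    "RateRow",
    "RateTable",
    "pairwise_differences",
    "divergence_rate",
    "format_rate",
    "branch_rate_table",
    "CALIBRATIONS",
]

#: Named node-age presets (Ma): the default recent-genomic scheme and the
#: alternative scheme used by the antecedent rate study.
CALIBRATIONS = {
    "default": {"chimp_human_split": 8.0, "chimp_bonobo_split": 2.0},
    "ref13": {"chimp_human_split": 7.5, "chimp_bonobo_split": 3.0},
}


def pairwise_differences(
    matrix: CharacterMatrix,
    taxon_a: str,
    taxon_b: str,
    major_only: bool = False,
    regions=None,
):
    """Count characters whose state sets are disjoint between two taxa.

    Returns ``(count, char_ids)``.  MISSING/INAPPLICABLE cells never count
    as differences.  ``regions`` filters by body region; ``major_only``
    restricts to presence/absence characters.
    """
    for t in (taxon_a, taxon_b):
        if t not in matrix.rows:
            raise KeyError(f"unknown taxon {t!r}")
    diffs = []
    for c in matrix.characters:
        if major_only and c.kind != "major":
            continue
        if regions is not None and c.region not in regions:
            continue
        a = matrix.cell(taxon_a, c.id)
        b = matrix.cell(taxon_b, c.id)
        if isinstance(a, _Sentinel) or isinstance(b, _Sentinel):
            continue
        if not (set(a) & set(b)):
            diffs.append(c.id)
    return len(diffs), diffs


def divergence_rate(n_changes: float, span_ma: float) -> float:
    """Changes per Ma over a span; raises unless the span is positive."""
    if span_ma <= 0:
        raise ValueError(f"span must be positive, got {span_ma}")
    return n_changes / span_ma


def format_rate(rate: float) -> str:
    """Display convention: 2 decimals below 1, 1 decimal at or above 1."""
    if abs(rate) >= 1:
        return f"{rate:.1f}"
    return f"{rate:.2f}"


@dataclass
class RateRow:
    scope: str  # branch / lineage / pair label
    n_changes: float
    span_ma: float
    rate: float

    @property
    def display(self) -> str:
        return format_rate(self.rate)


@dataclass
class RateTable:
    rows: list = field(default_factory=list)

    def row(self, scope: str) -> RateRow:
        for r in self.rows:
            if r.scope == scope:
                return r
        raise KeyError(f"no rate row for scope {scope!r}")

    def as_records(self) -> list:
        return [
            {
                "scope": r.scope,
                "n_changes": r.n_changes,
                "span_ma": r.span_ma,
                "rate": r.rate,
                "display": r.display,
            }
            for r in self.rows
        ]

    def to_tsv(self) -> str:
        lines = ["scope\tn_changes\tspan_ma\trate\tdisplay"]
        for r in self.rows:
            lines.append(f"{r.scope}\t{r.n_changes:g}\t{r.span_ma:g}\t{r.rate!r}\t{r.display}")
        return "\n".join(lines) + "\n"


def branch_rate_table(tree: PhyloTree, branch_counts: dict) -> RateTable:
    """Rates per branch and per root-to-tip lineage of an age-calibrated tree.

    ``branch_counts`` maps child-clade frozensets to change counts (as
    produced by a :class:`~morphoclad.reconstruction.ChangeMap`).  Every
    node must carry an age; zero-span branches are reported with a rate only
    when they also carry zero changes.
    """
    clades = tree.clades()
    for node, clade in clades.items():
        if node.age is None:
            raise TreeError(f"node {branch_name(clade)} has no age")
    table = RateTable()
    for parent, child in tree.edges():
        clade = clades[child]
        span = tree.branch_span(parent, child)
        n = branch_counts.get(clade, 0)
        if span <= 0:
            if n:
                raise ValueError(
                    f"{n} changes on zero-span branch {branch_name(clade)}"
                )
            continue
        table.rows.append(
            RateRow(
                scope=f"branch:{branch_name(clade)}",
                n_changes=n,
                span_ma=span,
                rate=divergence_rate(n, span),
            )
        )
    # root-to-tip lineage paths ("the human clade", "the chimpanzee clade")
    parents = {}
    for parent, child in tree.edges():
        parents[clades[child]] = (parent, child)
    for leaf in tree.leaves():
        clade = frozenset([leaf.label])
        n_total, span_total = 0.0, 0.0
        cursor = clade
        while cursor in parents:
            parent, child = parents[cursor]
            n_total += branch_counts.get(clades[child], 0)
            span_total += tree.branch_span(parent, child)
            cursor = clades[parent]
        if span_total > 0:
            table.rows.append(
                RateRow(
                    scope=f"lineage:{leaf.label}",
                    n_changes=n_total,
                    span_ma=span_total,
                    rate=divergence_rate(n_total, span_total),
                )
            )
    return table
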