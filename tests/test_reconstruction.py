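"""MPR enumeration, change mapping, direction and ambiguity."""

import numpy as np
import pytest

from morphoclad.matrix_io import CharacterDef, CharacterMatrix
from morphoclad.parsimony import fitch_length
from morphoclad.reconstruction import (
    classify_changes,
    enumerate_mprs,
    map_branch_changes,
    select_reconstruction,
    summarize_synapomorphies,
)
from morphoclad.synthetic import SyntheticSpec, generate_matrix, random_topology
from morphoclad.trees import parse_newick

from .oracles import brute_force_mprs

PAN = frozenset({"P_troglodytes", "P_paniscus"})
HOMPAN = frozenset({"P_troglodytes", "P_paniscus", "Homo"})
GREAT_APES = frozenset({"Pongo", "Gorilla", "P_troglodytes", "P_paniscus", "Homo"})


def mpr_change_sets(mprs):
    return {frozenset(r.key for r in m.changes) for m in mprs}


class TestEnumerateMprs:
    def test_char112_equal_parsimony_scenarios(self, tree, matrix):
        mprs = enumerate_mprs(tree, matrix, 112)
        assert len(mprs) >= 2
        assert all(m.total_changes == 3 for m in mprs)
        sets = mpr_change_sets(mprs)
        stem_gain = frozenset(
            {
                (112, GREAT_APES, 0, 1),
                (112, frozenset({"Homo"}), 1, 0),
                (112, frozenset({"P_paniscus"}), 1, 0),
            }
        )
        independent = frozenset(
            {
                (112, frozenset({"Pongo"}), 0, 1),
                (112, frozenset({"Gorilla"}), 0, 1),
                (112, frozenset({"P_troglodytes"}), 0, 1),
            }
        )
        assert stem_gain in sets and independent in sets

    def test_char66_two_reconstructions(self, tree, matrix):
        mprs = enumerate_mprs(tree, matrix, 66)
        assert len(mprs) == 2
        assert all(m.total_changes == 2 for m in mprs)
        sets = mpr_change_sets(mprs)
        assert frozenset(
            {(66, HOMPAN, 0, 1), (66, frozenset({"P_paniscus"}), 1, 0)}
        ) in sets
        assert frozenset(
            {(66, frozenset({"P_troglodytes"}), 0, 1), (66, frozenset({"Homo"}), 0, 1)}
        ) in sets

    def test_constant_character_single_empty_reconstruction(self, tree, matrix):
        mprs = enumerate_mprs(tree, matrix, 118)
        assert len(mprs) == 1 and mprs[0].total_changes == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_set_equals_brute_force_filter(self, seed):
        rng = np.random.default_rng(500 + seed)
        n = int(rng.integers(4, 7))
        labels = [f"T{i}" for i in range(n)]
        tr = random_topology(labels, rng)
        char = CharacterDef(id=1, state_labels=("0", "1", "2"))
        rows = {l: (frozenset([int(rng.integers(3))]),) for l in labels}
        m = CharacterMatrix(taxa=labels, characters=[char], rows=rows)
        mprs = enumerate_mprs(tr, m, 1)
        best, oracle_set = brute_force_mprs(tr, m, 1)
        assert {r.state_vector() for r in mprs} == oracle_set
        assert all(r.total_changes == best == fitch_length(tr, m, 1) for r in mprs)


class TestPolicies:
    def test_deltran_prefers_independent_terminal_gains(self, tree, matrix):
        mprs = enumerate_mprs(tree, matrix, 66)
        chosen = select_reconstruction(tree, mprs, policy="deltran")
        assert {r.child_clade for r in chosen.changes} == {
            frozenset({"P_troglodytes"}),
            frozenset({"Homo"}),
        }

    def test_acctran_prefers_stem_gain_with_reversal(self, tree, matrix):
        mprs = enumerate_mprs(tree, matrix, 66)
        chosen = select_reconstruction(tree, mprs, policy="acctran")
        assert {r.child_clade for r in chosen.changes} == {
            HOMPAN,
            frozenset({"P_paniscus"}),
        }

    def test_unknown_policy_rejected(self, tree, matrix):
        with pytest.raises(ValueError):
            select_reconstruction(tree, enumerate_mprs(tree, matrix, 66), policy="x")


class TestClassification:
    def test_gain_away_from_root_state_is_acquisition(self, tree, matrix):
        mprs = enumerate_mprs(tree, matrix, 66)
        chosen = select_reconstruction(tree, mprs, policy="deltran")
        classified = classify_changes(chosen.changes, chosen)
        assert all(r.direction == "acquisition" for r in classified)

    def test_pt_branch_changes_83_and_140_are_reversions(self, tree, matrix):
        cmap = map_branch_changes(tree, matrix, policy="deltran")
        pt = {
            r.char_id: r.direction
            for r in cmap.branch_records(frozenset({"P_troglodytes"}))
        }
        assert pt[83] == "reversion" and pt[140] == "reversion"

    def test_pan_stem_changes_are_reversions(self, tree, matrix):
        cmap = map_branch_changes(tree, matrix, policy="deltran")
        stem = {r.char_id: r.direction for r in cmap.branch_records(PAN)}
        assert stem == {120: "reversion", 131: "reversion"}

    def test_chimpanzee_clade_has_only_reversions(self, tree, matrix):
        """Every unambiguous change inside the Pan clade returns to the
        ancestral state; the clade acquires nothing new."""
        cmap = map_branch_changes(tree, matrix, policy="deltran")
        records = [r for r in cmap.clade_records(PAN) if not r.ambiguous]
        assert len(records) == 4
        assert all(r.direction == "reversion" for r in records)


class TestChangeMap:
    def test_bonobo_terminal_branch_is_static(self, tree, matrix):
        cmap = map_branch_changes(tree, matrix, policy="deltran")
        assert cmap.branch_records(frozenset({"P_paniscus"})) == []

    def test_pan_stem_carries_exactly_two_changes(self, tree, matrix):
        cmap = map_branch_changes(tree, matrix, policy="deltran")
        assert sorted(r.char_id for r in cmap.branch_records(PAN)) == [120, 131]

    def test_constant_matrix_maps_no_changes(self):
        t = parse_newick("((A,B),(C,D));")
        char = CharacterDef(id=1)
        m = CharacterMatrix(
            taxa=list("ABCD"),
            characters=[char],
            rows={x: (frozenset([0]),) for x in "ABCD"},
        )
        assert map_branch_changes(t, m).records == []

    @pytest.mark.parametrize("policy", ["deltran", "acctran"])
    def test_total_mapped_changes_equal_tree_length(self, tree, matrix, policy):
        cmap = map_branch_changes(tree, matrix, policy=policy)
        L = sum(fitch_length(tree, matrix, c.id) for c in matrix.characters)
        assert len(cmap.records) == L


class TestSynapomorphyTable:
    def test_pan_stem_lists_exactly_120_and_131(self, tree, matrix):
        table = summarize_synapomorphies(tree, matrix)
        entry = table[PAN]
        assert sorted(r.char_id for r in entry["unambiguous"]) == [120, 131]

    def test_char66_ambiguous_at_hompan_stem_with_alternatives(self, tree, matrix):
        table = summarize_synapomorphies(tree, matrix)
        cands = [d for d in table[HOMPAN]["ambiguous"] if d["char_id"] == 66]
        assert len(cands) == 1
        branches = {r.child_clade for r in cands[0]["placements"]}
        assert HOMPAN in branches
        assert frozenset({"P_troglodytes"}) in branches
        assert frozenset({"Homo"}) in branches

    def test_homoplasy_free_synthetic_is_fully_unambiguous(self):
        data = generate_matrix(
            SyntheticSpec(n_taxa=8, n_characters=40, rate_per_branch=0.02, seed=1)
        )
        table = summarize_synapomorphies(data.tree, data.matrix)
        n_unamb = sum(len(e["unambiguous"]) for e in table.values())
        assert all(not e["ambiguous"] for e in table.values())
        L = sum(
            fitch_length(data.tree, data.matrix, c.id) for c in data.matrix.characters
        )
        assert n_unamb == L
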