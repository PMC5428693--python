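"""Parsimony scoring, homoplasy indices and exact tree search."""

import dendropy
import numpy as np
import pytest
from dendropy.model.parsimony import fitch_down_pass

from morphoclad.matrix_io import (
    CharacterDef,
    CharacterMatrix,
    MISSING,
    write_matrix,
)
from morphoclad.parsimony import (
    branch_and_bound_search,
    char_max_steps,
    char_min_steps,
    ensemble_indices,
    exhaustive_search,
    fitch_length,
)
from morphoclad.synthetic import SyntheticSpec, generate_matrix, random_topology
from morphoclad.trees import TreeError, parse_newick, write_newick

from .oracles import brute_force_min_length, star_tree_length


def random_matrix(rng, n_taxa, n_chars, n_states=2, p_missing=0.0):
    taxa = [f"T{i}" for i in range(n_taxa)]
    chars = [
        CharacterDef(id=j + 1, state_labels=tuple(str(s) for s in range(n_states)))
        for j in range(n_chars)
    ]
    rows = {}
    for t in taxa:
        cells = []
        for _ in chars:
            if rng.random() < p_missing:
                cells.append(MISSING)
            else:
                cells.append(frozenset([int(rng.integers(n_states))]))
        rows[t] = tuple(cells)
    return CharacterMatrix(taxa=taxa, characters=chars, rows=rows)


def random_tree(rng, labels):
    return random_topology(labels, rng)


class TestFitchLength:
    def test_char112_pattern_needs_three_steps(self, tree, matrix):
        assert fitch_length(tree, matrix, 112) == 3

    def test_char66_pattern_needs_two_steps(self, tree, matrix):
        assert fitch_length(tree, matrix, 66) == 2

    def test_constant_character_is_free(self, tree, matrix):
        assert fitch_length(tree, matrix, 118) == 0

    def test_missing_tip_never_forces_a_step(self):
        t = parse_newick("((A,B),(C,D));")
        char = CharacterDef(id=1)
        rows = {
            "A": (frozenset([0]),),
            "B": (frozenset([0]),),
            "C": (MISSING,),
            "D": (frozenset([0]),),
        }
        m = CharacterMatrix(taxa=list("ABCD"), characters=[char], rows=rows)
        assert fitch_length(t, m, 1) == 0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_assignment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        m = random_matrix(rng, n, 1, n_states=3, p_missing=0.1)
        tr = random_tree(rng, m.taxa)
        assert fitch_length(tr, m, 1) == brute_force_min_length(tr, m, 1)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dendropy_fitch(self, seed):
        """Independent library cross-check of total tree length."""
        rng = np.random.default_rng(100 + seed)
        m = random_matrix(rng, 6, 8, n_states=2)
        tr = random_tree(rng, m.taxa)
        ours = sum(fitch_length(tr, m, c.id) for c in m.characters)

        taxa = dendropy.TaxonNamespace()
        dmat = dendropy.StandardCharacterMatrix.get(
            data=write_matrix(m), schema="nexus", taxon_namespace=taxa
        )
        dtree = dendropy.Tree.get(
            data=write_newick(tr), schema="newick", taxon_namespace=taxa
        )
        theirs = fitch_down_pass(
            dtree.postorder_node_iter(),
            taxon_state_sets_map=dmat.taxon_state_sets_map(gaps_as_missing=True),
        )
        assert ours == theirs


class TestStepBounds:
    def test_binary_with_both_states_needs_one(self):
        m = random_matrix(np.random.default_rng(0), 4, 1)
        while char_min_steps(m, 1) == 0:  # ensure both states present
            m = random_matrix(np.random.default_rng(1), 4, 1)
        assert char_min_steps(m, 1) == 1

    def test_three_observed_states_need_two(self):
        chars = [CharacterDef(id=1, state_labels=("0", "1", "2"))]
        rows = {t: (frozenset([s]),) for t, s in zip("ABC", [0, 1, 2])}
        m = CharacterMatrix(taxa=list("ABC"), characters=chars, rows=rows)
        assert char_min_steps(m, 1) == 2

    def test_all_missing_is_zero(self):
        chars = [CharacterDef(id=1)]
        m = CharacterMatrix(
            taxa=list("AB"), characters=chars, rows={"A": (MISSING,), "B": (MISSING,)}
        )
        assert char_min_steps(m, 1) == 0
        assert char_max_steps(m, 1) == 0

    def test_polymorphic_tip_does_not_inflate_min_steps(self):
        chars = [CharacterDef(id=1)]
        rows = {"A": (frozenset([0, 1]),), "B": (frozenset([0]),), "C": (frozenset([0]),)}
        m = CharacterMatrix(taxa=list("ABC"), characters=chars, rows=rows)
        assert char_min_steps(m, 1) == 0  # state 0 serves every tip

    def test_star_tree_count_seven_three_split(self):
        chars = [CharacterDef(id=1)]
        taxa = [f"T{i}" for i in range(10)]
        rows = {t: (frozenset([0 if i < 7 else 1]),) for i, t in enumerate(taxa)}
        m = CharacterMatrix(taxa=taxa, characters=chars, rows=rows)
        assert char_max_steps(m, 1) == 3

    @pytest.mark.parametrize("seed", range(8))
    def test_max_steps_equals_star_tree_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        m = random_matrix(rng, 6, 1, n_states=3, p_missing=0.15)
        assert char_max_steps(m, 1) == star_tree_length(m, 1)

    @pytest.mark.parametrize("seed", range(10))
    def test_min_le_steps_le_max_on_any_tree(self, seed):
        rng = np.random.default_rng(300 + seed)
        m = random_matrix(rng, 6, 4, n_states=3, p_missing=0.1)
        tr = random_tree(rng, m.taxa)
        for c in m.characters:
            s = fitch_length(tr, m, c.id)
            assert char_min_steps(m, c.id) <= s <= char_max_steps(m, c.id)


class TestEnsembleIndices:
    def test_homoplasy_free_matrix_scores_perfect(self):
        data = generate_matrix(
            SyntheticSpec(n_taxa=8, n_characters=40, rate_per_branch=0.02, seed=1)
        )
        score = ensemble_indices(data.tree, data.matrix)
        # this seed yields a homoplasy-free realization: s_i == m_i for all i
        assert all(
            score.per_character_steps[c.id] == char_min_steps(data.matrix, c.id)
            for c in data.matrix.characters
        )
        assert score.ci_percent == 100 and score.ri_percent == 100

    def test_hand_computed_small_matrix(self):
        # ((A,B),(C,D)): char1 splits AB|CD (s=1,m=1,g=2); char2 splits
        # AC|BD (s=2,m=1,g=2); char3 constant (s=0,m=0,g=0); char4 autapomorphy
        # (s=1,m=1,g=1). L=4, CI=(1+1+0+1)/4=0.75,
        # RI over informative chars 1,2: (4-3)/(4-2)=0.5
        t = parse_newick("((A,B),(C,D));")
        chars = [CharacterDef(id=i) for i in (1, 2, 3, 4)]
        cols = {
            1: dict(zip("ABCD", [0, 0, 1, 1])),
            2: dict(zip("ABCD", [0, 1, 0, 1])),
            3: dict(zip("ABCD", [0, 0, 0, 0])),
            4: dict(zip("ABCD", [1, 0, 0, 0])),
        }
        rows = {t_: tuple(frozenset([cols[c.id][t_]]) for c in chars) for t_ in "ABCD"}
        m = CharacterMatrix(taxa=list("ABCD"), characters=chars, rows=rows)
        score = ensemble_indices(t, m)
        assert score.length == 4
        assert score.ci == pytest.approx(0.75)
        assert score.ri == pytest.approx(0.5)
        assert (score.ci_percent, score.ri_percent) == (75, 50)

    def test_undefined_ci_flagged_at_zero_length(self):
        t = parse_newick("(A,B);")
        chars = [CharacterDef(id=1)]
        m = CharacterMatrix(
            taxa=["A", "B"],
            characters=chars,
            rows={"A": (frozenset([0]),), "B": (frozenset([0]),)},
        )
        score = ensemble_indices(t, m)
        assert score.undefined_ci and score.ci_percent == 100


class TestSearch:
    @pytest.mark.parametrize("seed", range(10))
    def test_branch_and_bound_equals_exhaustive(self, seed):
        rng = np.random.default_rng(400 + seed)
        n = int(rng.integers(4, 8))
        m = random_matrix(rng, n, int(rng.integers(3, 7)))
        bb_trees, bb_score = branch_and_bound_search(m, outgroup=m.taxa[0])
        ex_trees, ex_score = exhaustive_search(m, outgroup=m.taxa[0])
        assert bb_score.length == ex_score.length
        assert [t.topology_key() for t in bb_trees] == [
            t.topology_key() for t in ex_trees
        ]

    def test_perfect_phylogeny_recovered_uniquely(self):
        data = generate_matrix(
            SyntheticSpec(n_taxa=8, n_characters=40, rate_per_branch=0.02, seed=1)
        )
        og = data.matrix.taxa[0]
        trees, score = branch_and_bound_search(data.matrix, outgroup=og)
        from morphoclad.trees import reroot

        keys = {t.topology_key() for t in trees}
        assert reroot(data.tree, og).topology_key() in keys
        assert score.length == sum(
            char_min_steps(data.matrix, c.id) for c in data.matrix.characters
        )

    def test_uninformative_character_shifts_length_not_topology(self):
        rng = np.random.default_rng(77)
        m = random_matrix(rng, 6, 5)
        trees1, score1 = branch_and_bound_search(m, outgroup=m.taxa[0])
        # append an autapomorphy (uninformative, fixed cost 1)
        extra = CharacterDef(id=99)
        chars = m.characters + [extra]
        rows = {
            t: m.rows[t] + (frozenset([1 if t == m.taxa[1] else 0]),) for t in m.taxa
        }
        m2 = CharacterMatrix(taxa=m.taxa, characters=chars, rows=rows)
        trees2, score2 = branch_and_bound_search(m2, outgroup=m.taxa[0])
        assert score2.length == score1.length + 1
        assert {t.topology_key() for t in trees2} == {t.topology_key() for t in trees1}

    def test_taxon_ceiling_and_minimum(self):
        rng = np.random.default_rng(1)
        with pytest.raises(TreeError):
            branch_and_bound_search(random_matrix(rng, 17, 2), outgroup="T0")
        with pytest.raises(TreeError):
            branch_and_bound_search(random_matrix(rng, 2, 2), outgroup="T0")
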