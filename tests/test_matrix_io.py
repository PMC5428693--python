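"""Character-matrix parsing, writing, validation and round trips."""

import numpy as np
import pytest

from morphoclad.matrix_io import (
    INAPPLICABLE,
    MISSING,
    CharacterDef,
    CharacterMatrix,
    ParseError,
    UnrepresentableError,
    read_matrix,
    validate_matrix,
    write_matrix,
)

MINIMAL_NEXUS = """#NEXUS
BEGIN DATA;
  DIMENSIONS NTAX=2 NCHAR=1;
  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;
  MATRIX
    A 0
    B 1
  ;
END;
"""


def random_matrix(rng, n_taxa=8, n_chars=20):
    taxa = [f"T{i:02d}" for i in range(n_taxa)]
    characters = []
    rows = {t: [] for t in taxa}
    for j in range(n_chars):
        n_states = int(rng.integers(2, 4))
        characters.append(
            CharacterDef(
                id=j + 1,
                label=f"character {j + 1}",
                state_labels=tuple(str(s) for s in range(n_states)),
                kind=["major", "minor"][int(rng.integers(2))],
                region=["HN", "FL", "HL", "trunk"][int(rng.integers(4))],
            )
        )
        for t in taxa:
            roll = rng.random()
            if roll < 0.05:
                rows[t].append(MISSING)
            elif roll < 0.1:
                rows[t].append(INAPPLICABLE)
            elif roll < 0.2:
                k = int(rng.integers(2, n_states + 1))
                rows[t].append(frozenset(rng.choice(n_states, size=k, replace=False).tolist()))
            else:
                rows[t].append(frozenset([int(rng.integers(n_states))]))
    return CharacterMatrix(
        taxa=taxa, characters=characters, rows={t: tuple(r) for t, r in rows.items()}
    )


class TestReadNexus:
    def test_minimal_two_taxon_file(self):
        m = read_matrix(MINIMAL_NEXUS)
        assert m.taxa == ["A", "B"]
        assert m.cell("A", 1) == frozenset([0])
        assert m.cell("B", 1) == frozenset([1])

    def test_polymorphism_missing_and_gap_tokens(self):
        nex = MINIMAL_NEXUS.replace("A 0", "A {01}").replace("B 1", "B ?")
        m = read_matrix(nex)
        assert m.cell("A", 1) == frozenset([0, 1])
        assert m.cell("B", 1) is MISSING
        nex = MINIMAL_NEXUS.replace("A 0", "A -")
        assert read_matrix(nex).cell("A", 1) is INAPPLICABLE

    @pytest.mark.parametrize(
        "mutation",
        [
            lambda s: s.replace("B 1", "A 1"),  # duplicate taxon
            lambda s: s.replace("B 1", "B 2"),  # symbol outside alphabet
            lambda s: s.replace("#NEXUS", ""),  # missing header
        ],
    )
    def test_malformed_input_raises_parse_error(self, mutation):
        with pytest.raises(ParseError):
            read_matrix(mutation(MINIMAL_NEXUS))


class TestWrite:
    def test_missing_cell_emits_question_mark(self):
        m = read_matrix(MINIMAL_NEXUS)
        rows = dict(m.rows)
        rows["A"] = (MISSING,)
        m2 = CharacterMatrix(taxa=m.taxa, characters=m.characters, rows=rows)
        out = write_matrix(m2)
        assert "A  ?" in out.replace("   ", "  ")

    def test_empty_character_matrix_round_trips(self):
        m = CharacterMatrix(taxa=["A", "B"], characters=[], rows={"A": (), "B": ()})
        assert read_matrix(write_matrix(m)) == m

    def test_state_beyond_symbol_alphabet_is_unrepresentable(self):
        c = CharacterDef(id=1, state_labels=tuple(str(i) for i in range(11)))
        m = CharacterMatrix(
            taxa=["A"], characters=[c], rows={"A": (frozenset([10]),)}
        )
        with pytest.raises(UnrepresentableError):
            write_matrix(m)


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(8))
    def test_nexus_round_trip_is_identity(self, seed):
        m = random_matrix(np.random.default_rng(seed))
        assert read_matrix(write_matrix(m, "nexus"), "nexus") == m

    @pytest.mark.parametrize("seed", range(4))
    def test_csv_round_trip_is_identity(self, seed):
        m = random_matrix(np.random.default_rng(100 + seed))
        text = write_matrix(m, "csv")
        assert read_matrix(text, "csv", characters=m.characters) == m

    def test_csv_tokens(self):
        csv = "taxon,1,2,3\nA,0/1,?,-\nB,1,0,2\n"
        m = read_matrix(csv, "csv")
        assert m.cell("A", 1) == frozenset([0, 1])
        assert m.cell("A", 2) is MISSING
        assert m.cell("A", 3) is INAPPLICABLE
        assert m.cell("B", 3) == frozenset([2])

    def test_fixture_matrix_round_trips(self, matrix):
        assert read_matrix(write_matrix(matrix)) == matrix


class TestValidate:
    def test_valid_fixture_matrix(self, matrix):
        assert validate_matrix(matrix) == []

    def test_out_of_domain_state_flagged(self):
        c = CharacterDef(id=1)  # binary
        m = CharacterMatrix(taxa=["A"], characters=[c], rows={"A": (frozenset([2]),)})
        problems = validate_matrix(m)
        assert len(problems) == 1 and "char 1" in problems[0]

    def test_duplicate_taxon_flagged(self):
        c = CharacterDef(id=1)
        m = CharacterMatrix(
            taxa=["A", "A"], characters=[c], rows={"A": (frozenset([0]),)}
        )
        assert any("duplicate taxon" in p for p in validate_matrix(m))

    def test_parser_rejects_what_validate_flags(self):
        # the parser never silently coerces an invalid file
        nex = MINIMAL_NEXUS.replace("B 1", "B 2")
        with pytest.raises(ParseError):
            read_matrix(nex)
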