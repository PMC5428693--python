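"""Coded character matrices: types, validation, NEXUS and CSV input/output.

A :class:`CharacterMatrix` holds unordered discrete states for a set of
terminal taxa.  Each cell is a non-empty frozenset of integer states
(singleton = fixed observation, larger = polymorphism), or one of the
sentinels :data:`MISSING` (``?``: no observation) and :data:`INAPPLICABLE`
(``-``: the character cannot be scored, e.g. an attachment detail of a
muscle that is absent).  Both sentinels behave as full-domain wildcards in
parsimony scoring; they differ only in reporting.

NEXUS reading is delegated to dendropy; writing produces a canonical DATA
block plus a private ``MORPHOCLAD`` block carrying per-character metadata
(major/minor kind, body region) that standard readers skip.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace

import dendropy
import pandas as pd

__all__ = [
    "MISSING",
    "INAPPLICABLE",
    "CharacterDef",
    "CharacterMatrix",
    "MatrixError",
    "ParseError",
    "UnrepresentableError",
    "read_matrix",
    "write_matrix",
    "validate_matrix",
]

KINDS = ("major", "minor")
REGIONS = ("HN", "FL", "HL", "trunk")

_LABEL_RE = re.compile(r"^[A-Za-z0-9_.\-]+$")


class MatrixError(ValueError):
    """Base class for character-matrix errors."""


class ParseError(MatrixError):
    """Raised when a NEXUS/CSV source cannot be parsed."""


class UnrepresentableError(MatrixError):
    """Raised when a matrix cannot be expressed in the requested dialect."""


class _Sentinel:
    __slots__ = ("name", "token")

    def __init__(self, name: str, token: str):
        self.name = name
        self.token = token

    def __repr__(self) -> str:
        return self.name

    def __deepcopy__(self, memo):
        return self

    def __copy__(self):
        return self


#: No observation for this taxon/character.
MISSING = _Sentinel("MISSING", "?")
#: Character cannot be scored for this taxon (e.g. muscle absent).
INAPPLICABLE = _Sentinel("INAPPLICABLE", "-")

Cell = "frozenset[int] | _Sentinel"


@dataclass(frozen=True)
class CharacterDef:
    """One character: integer id, free-text label, state domain, metadata.

    ``kind`` separates major characters (muscle presence/absence) from minor
    ones (attachment, belly, fusion detail); ``region`` is the body region
    (head-neck HN, forelimb FL, hindlimb HL, trunk).
    """

    id: int
    label: str = ""
    state_labels: tuple = ("0", "1")
    kind: str = "minor"
    region: str = "HN"

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def domain(self) -> frozenset:
        return frozenset(range(self.n_states))


@dataclass
class CharacterMatrix:
    """Taxa x characters table of unordered discrete state sets."""

    taxa: list = field(default_factory=list)
    characters: list = field(default_factory=list)
    # taxon label -> tuple of cells, aligned with `characters`
    rows: dict = field(default_factory=dict)

    # -- accessors ---------------------------------------------------------

    def char_index(self, char_id: int) -> int:
        for i, c in enumerate(self.characters):
            if c.id == char_id:
                return i
        raise KeyError(f"no character with id {char_id}")

    def char_by_id(self, char_id: int) -> CharacterDef:
        return self.characters[self.char_index(char_id)]

    def cell(self, taxon: str, char_id: int):
        if taxon not in self.rows:
            raise KeyError(f"unknown taxon {taxon!r}")
        return self.rows[taxon][self.char_index(char_id)]

    def column(self, char_id: int) -> dict:
        """Raw cells of one character, keyed by taxon."""
        i = self.char_index(char_id)
        return {t: self.rows[t][i] for t in self.taxa}

    def state_sets(self, char_id: int) -> dict:
        """Cells as frozensets; MISSING/INAPPLICABLE widen to the full domain."""
        char = self.char_by_id(char_id)
        out = {}
        for t, cell in self.column(char_id).items():
            out[t] = char.domain if isinstance(cell, _Sentinel) else frozenset(cell)
        return out

    def scorable_sets(self, char_id: int) -> dict:
        """Like :meth:`state_sets` but with MISSING/INAPPLICABLE tips dropped."""
        out = {}
        for t, cell in self.column(char_id).items():
            if not isinstance(cell, _Sentinel):
                out[t] = frozenset(cell)
        return out

    def subset(self, kinds=None, regions=None) -> "CharacterMatrix":
        """Matrix restricted to characters of the given kinds/regions."""
        keep = [
            i
            for i, c in enumerate(self.characters)
            if (kinds is None or c.kind in kinds)
            and (regions is None or c.region in regions)
        ]
        return CharacterMatrix(
            taxa=list(self.taxa),
            characters=[self.characters[i] for i in keep],
            rows={t: tuple(self.rows[t][i] for i in keep) for t in self.taxa},
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.characters == other.characters
            and self.rows == other.rows
        )


def matrix_from_columns(taxa, characters, columns) -> CharacterMatrix:
    """Assemble a matrix from per-character {taxon: cell} dicts."""
    rows = {}
    for t in taxa:
        rows[t] = tuple(columns[c.id][t] for c in characters)
    return CharacterMatrix(taxa=list(taxa), characters=list(characters), rows=rows)


# -- validation ------------------------------------------------------------


def validate_matrix(matrix: CharacterMatrix) -> list:
    """Return a list of human-readable invariant violations (empty = valid)."""
    violations = []
    seen = set()
    for t in matrix.taxa:
        if not t or not _LABEL_RE.match(t):
            violations.append(f"taxon label {t!r} is empty or contains invalid characters")
        if t in seen:
            violations.append(f"duplicate taxon label {t!r}")
        seen.add(t)
        if t not in matrix.rows:
            violations.append(f"taxon {t!r} has no row")
    for t in matrix.rows:
        if t not in seen:
            violations.append(f"row for unlisted taxon {t!r}")
    ids = set()
    for c in matrix.characters:
        if c.id in ids:
            violations.append(f"duplicate character id {c.id}")
        ids.add(c.id)
        if c.n_states < 1:
            violations.append(f"character {c.id} declares no states")
        if c.kind not in KINDS:
            violations.append(f"character {c.id} has unknown kind {c.kind!r}")
        if c.region not in REGIONS:
            violations.append(f"character {c.id} has unknown region {c.region!r}")
    for t in matrix.taxa:
        row = matrix.rows.get(t)
        if row is None:
            continue
        if len(row) != len(matrix.characters):
            violations.append(
                f"row for {t!r} has {len(row)} cells, expected {len(matrix.characters)}"
            )
            continue
        for c, cell in zip(matrix.characters, row):
            if isinstance(cell, _Sentinel):
                continue
            if not cell:
                violations.append(f"empty state set at ({t!r}, char {c.id})")
            elif not set(cell) <= c.domain:
                bad = sorted(set(cell) - c.domain)
                violations.append(
                    f"state(s) {bad} at ({t!r}, char {c.id}) outside domain 0..{c.n_states - 1}"
                )
    return violations


# -- NEXUS -----------------------------------------------------------------

_META_BLOCK_RE = re.compile(r"BEGIN\s+MORPHOCLAD\s*;(.*?)END\s*;", re.I | re.S)


def _quote(text: str) -> str:
    return "'" + text.replace("'", "''") + "'"


def _split_commands(block: str):
    """Split a MORPHOCLAD block body into ;-terminated commands, respecting quotes."""
    cmd, in_quote = [], False
    for ch in block:
        if ch == "'":
            in_quote = not in_quote
            cmd.append(ch)
        elif ch == ";" and not in_quote:
            text = "".join(cmd).strip()
            if text:
                yield text
            cmd = []
        else:
            cmd.append(ch)
    tail = "".join(cmd).strip()
    if tail:
        yield tail


_META_FIELD_RE = re.compile(r"(\w+)=('(?:[^']|'')*'|\S+)")


def _parse_meta_block(source: str) -> dict:
    """index (1-based) -> dict of metadata fields from the MORPHOCLAD block."""
    m = _META_BLOCK_RE.search(source)
    if not m:
        return {}
    meta = {}
    for cmd in _split_commands(m.group(1)):
        parts = cmd.split(None, 2)
        if not parts or parts[0].upper() != "CHARMETA":
            continue
        if len(parts) < 2:
            raise ParseError(f"malformed CHARMETA command: {cmd!r}")
        try:
            index = int(parts[1])
        except ValueError as exc:
            raise ParseError(f"CHARMETA index is not an integer in {cmd!r}") from exc
        fields = {}
        for key, raw in _META_FIELD_RE.findall(parts[2] if len(parts) > 2 else ""):
            if raw.startswith("'"):
                raw = raw[1:-1].replace("''", "'")
            fields[key.lower()] = raw
        meta[index] = fields
    return meta


_EMPTY_DIM_RE = re.compile(r"DIMENSIONS\s+NTAX=\d+\s+NCHAR=0\s*;", re.I)


def _read_nexus(source: str) -> CharacterMatrix:
    if _EMPTY_DIM_RE.search(source):
        # zero-character matrix: taxon labels only (dendropy requires NCHAR>0)
        block = re.search(r"MATRIX(.*?);", source, re.S | re.I)
        taxa = [ln.split()[0] for ln in (block.group(1) if block else "").splitlines()
                if ln.strip()]
        if len(set(taxa)) != len(taxa):
            raise ParseError("duplicate taxon labels in NEXUS matrix")
        return CharacterMatrix(taxa=taxa, characters=[], rows={t: () for t in taxa})
    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=source, schema="nexus")
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise ParseError(f"NEXUS parse failed: {exc}") from exc
    taxa = [t.label.replace(" ", "_") for t in dmat.taxon_namespace]
    if len(set(taxa)) != len(taxa):
        raise ParseError("duplicate taxon labels in NEXUS matrix")
    nchar = max((len(dmat[t]) for t in dmat.taxon_namespace), default=0)
    # matrix-wide symbol alphabet defines the default state domain
    symbols = []
    for sa in dmat.state_alphabets or [dmat.default_state_alphabet]:
        for sym in sa.fundamental_symbol_iter():
            if sym not in ("?", "-") and sym not in symbols:
                symbols.append(sym)
    meta = _parse_meta_block(source)
    characters = []
    for i in range(nchar):
        fields = meta.get(i + 1, {})
        state_labels = tuple(fields["states"].split("|")) if "states" in fields else tuple(symbols)
        characters.append(
            CharacterDef(
                id=int(fields.get("id", i + 1)),
                label=fields.get("label", ""),
                state_labels=state_labels or ("0",),
                kind=fields.get("kind", "minor"),
                region=fields.get("region", "HN"),
            )
        )
    rows = {}
    for dtaxon, label in zip(dmat.taxon_namespace, taxa):
        cells = []
        for j, st in enumerate(dmat[dtaxon]):
            if st.symbol == "?":
                cells.append(MISSING)
            elif st.symbol == "-":
                cells.append(INAPPLICABLE)
            elif st.symbol is not None:
                try:
                    cells.append(frozenset([int(st.symbol)]))
                except ValueError as exc:
                    raise ParseError(
                        f"non-integer state symbol {st.symbol!r} at ({label}, char {j + 1})"
                    ) from exc
            else:  # polymorphic / uncertain set like {01}
                members = [m.symbol for m in st.member_states if m.symbol not in ("?", "-")]
                cells.append(frozenset(int(s) for s in members))
        rows[label] = tuple(cells)
    matrix = CharacterMatrix(taxa=taxa, characters=characters, rows=rows)
    problems = validate_matrix(matrix)
    if problems:
        raise ParseError("invalid NEXUS matrix: " + "; ".join(problems))
    return matrix


def _cell_token_nexus(cell) -> str:
    if cell is MISSING:
        return "?"
    if cell is INAPPLICABLE:
        return "-"
    states = sorted(cell)
    if any(s > 9 or s < 0 for s in states):
        raise UnrepresentableError(f"state {max(states)} exceeds NEXUS symbol alphabet 0-9")
    if len(states) == 1:
        return str(states[0])
    return "{" + "".join(str(s) for s in states) + "}"


def _write_nexus(matrix: CharacterMatrix) -> str:
    problems = validate_matrix(matrix)
    if problems:
        raise MatrixError("cannot write invalid matrix: " + "; ".join(problems))
    nstates = max((c.n_states for c in matrix.characters), default=2)
    if nstates > 10:
        raise UnrepresentableError("more than 10 states cannot use the 0-9 symbol alphabet")
    symbols = "".join(str(s) for s in range(max(nstates, 2)))
    out = io.StringIO()
    out.write("#NEXUS\n\nBEGIN DATA;\n")
    out.write(
        f"  DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={len(matrix.characters)};\n"
    )
    out.write(f'  FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\n')
    out.write("  MATRIX\n")
    width = max((len(t) for t in matrix.taxa), default=0)
    for t in matrix.taxa:
        tokens = "".join(_cell_token_nexus(c) for c in matrix.rows[t])
        out.write(f"    {t:<{width}}  {tokens}\n")
    out.write("  ;\nEND;\n\nBEGIN MORPHOCLAD;\n")
    for i, c in enumerate(matrix.characters, start=1):
        states = _quote("|".join(c.state_labels))
        out.write(
            f"  CHARMETA {i} id={c.id} kind={c.kind} region={c.region} "
            f"label={_quote(c.label)} states={states};\n"
        )
    out.write("END;\n")
    return out.getvalue()


# -- CSV -------------------------------------------------------------------


def _parse_csv_token(token: str, taxon: str, char_id) -> object:
    token = token.strip()
    if token == "?":
        return MISSING
    if token == "-":
        return INAPPLICABLE
    try:
        return frozenset(int(p) for p in token.split("/"))
    except ValueError as exc:
        raise ParseError(
            f"unparseable cell token {token!r} at ({taxon!r}, char {char_id})"
        ) from exc


def _read_csv(source: str, characters=None) -> CharacterMatrix:
    try:
        df = pd.read_csv(io.StringIO(source), index_col=0, dtype=str)
    except Exception as exc:
        raise ParseError(f"CSV parse failed: {exc}") from exc
    taxa = [str(t) for t in df.index]
    if len(set(taxa)) != len(taxa):
        raise ParseError("duplicate taxon labels in CSV matrix")
    if characters is None:
        characters = []
        for col in df.columns:
            try:
                cid = int(col)
            except ValueError as exc:
                raise ParseError(f"CSV column header {col!r} is not a character id") from exc
            characters.append(CharacterDef(id=cid))
    elif len(characters) != len(df.columns):
        raise ParseError(
            f"{len(characters)} character definitions supplied for {len(df.columns)} columns"
        )
    rows = {}
    for t in taxa:
        cells = []
        for c, token in zip(characters, df.loc[t]):
            if pd.isna(token):
                cells.append(MISSING)
                continue
            cells.append(_parse_csv_token(str(token), t, c.id))
        rows[t] = tuple(cells)
    # widen binary defaults so every observed state fits the domain
    widened = []
    for j, c in enumerate(characters):
        observed = set()
        for t in taxa:
            cell = rows[t][j]
            if not isinstance(cell, _Sentinel):
                observed |= set(cell)
        need = max(observed, default=0) + 1
        if need > c.n_states:
            c = replace(c, state_labels=tuple(str(s) for s in range(need)))
        widened.append(c)
    matrix = CharacterMatrix(taxa=taxa, characters=widened, rows=rows)
    problems = validate_matrix(matrix)
    if problems:
        raise ParseError("invalid CSV matrix: " + "; ".join(problems))
    return matrix


def _write_csv(matrix: CharacterMatrix) -> str:
    problems = validate_matrix(matrix)
    if problems:
        raise MatrixError("cannot write invalid matrix: " + "; ".join(problems))

    def token(cell):
        if cell is MISSING:
            return "?"
        if cell is INAPPLICABLE:
            return "-"
        return "/".join(str(s) for s in sorted(cell))

    out = io.StringIO()
    out.write("taxon," + ",".join(str(c.id) for c in matrix.characters) + "\n")
    for t in matrix.taxa:
        out.write(t + "," + ",".join(token(c) for c in matrix.rows[t]) + "\n")
    return out.getvalue()


# -- public API ------------------------------------------------------------


def read_matrix(source: str, dialect: str = "nexus", characters=None) -> CharacterMatrix:
    """Parse a character matrix from NEXUS or CSV text.

    Parameters
    ----------
    source:
        File content (not a path).
    dialect:
        ``"nexus"`` or ``"csv"``.
    characters:
        Optional list of :class:`CharacterDef` supplying metadata for CSV
        columns (CSV itself carries only ids).
    """
    if dialect == "nexus":
        return _read_nexus(source)
    if dialect == "csv":
        return _read_csv(source, characters=characters)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_matrix(matrix: CharacterMatrix, dialect: str = "nexus") -> str:
    """Serialize a matrix; output is re-readable by :func:`read_matrix`."""
    if dialect == "nexus":
        return _write_nexus(matrix)
    if dialect == "csv":
        return _write_csv(matrix)
    raise ValueError(f"unknown dialect {dialect!r}")
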