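"""Majority-rule coding of specimen-level observations into character states.

The coding rule: a state is assigned to a terminal taxon when it is found
in at least 50% of the counted units.  Units are dissected specimens by
default; side-based counting (each observed body side is one unit) is
available because published tallies often count sides.  Under specimen
counting, a bilaterally asymmetric specimen (a state on one side only)
contributes weight 0.5 to each side's state.

For binary presence/absence characters an exact 50:50 split codes the
conventional presence state (the rule is inclusive); multistate ties code
as a polymorphic state set, which parsimony handles natively.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import pandas as pd

from .matrix_io import (
    CharacterDef,
    CharacterMatrix,
    MISSING,
    ParseError,
    matrix_from_columns,
)

__all__ = [
    "SpecimenObservations",
    "ConflictError",
    "code_majority",
    "merge_specimen_sources",
    "read_observations_csv",
    "code_matrix",
]


class ConflictError(ValueError):
    """Same specimen id reported with different records across sources."""


@dataclass(frozen=True)
class SpecimenObservations:
    """Observations for one dissected specimen.

    ``records`` maps character id to either a single state (both sides
    agree or only one observation exists), a ``(left, right)`` pair of
    states with ``None`` for an unobserved side, or is simply absent when
    the character was not scored.
    """

    taxon: str
    specimen_id: str
    records: tuple = ()  # tuple of (char_id, observation) pairs; hashable

    def record_dict(self) -> dict:
        return dict(self.records)


def _unit_weights(observation, unit: str):
    """Yield (state, weight) contributions of one specimen's observation."""
    if observation is None:
        return
    if isinstance(observation, tuple):
        sides = [s for s in observation if s is not None]
        if len(observation) > 2:
            raise ValueError("side-specific records carry at most two entries")
        if not sides:
            return
        if unit == "side":
            for s in sides:
                yield s, 1.0
        else:  # one specimen = one unit, split across disagreeing sides
            for s in sides:
                yield s, 1.0 / len(sides)
    else:
        if unit == "side":
            yield observation, 1.0
        else:
            yield observation, 1.0


def code_majority(
    observations,
    character: CharacterDef,
    unit: str = "specimen",
    presence_state: int = 1,
):
    """Code one taxon's state set for one character by the >=50% rule.

    Returns a frozenset (singleton normally, larger on unresolved multistate
    ties) or MISSING when no specimen was scored.  ``presence_state`` is the
    state treated as "present" for the inclusive boundary on two-state
    characters.
    """
    if unit not in ("specimen", "side"):
        raise ValueError(f"unknown counting unit {unit!r}")
    weights = {}
    for spec in observations:
        obs = spec.record_dict().get(character.id)
        for state, w in _unit_weights(obs, unit):
            weights[state] = weights.get(state, 0.0) + w
    total = sum(weights.values())
    if total == 0:
        warnings.warn(
            f"no observations for character {character.id}; coding MISSING",
            stacklevel=2,
        )
        return MISSING
    top = max(weights.values())
    winners = {s for s, w in weights.items() if w == top}
    if len(winners) == 1:
        return frozenset(winners)
    # exact tie: on a two-state character the presence state wins (the rule
    # "present in >= 50% of specimens" is inclusive); otherwise polymorphic
    if character.n_states == 2 and presence_state in winners:
        return frozenset([presence_state])
    return frozenset(winners)


def merge_specimen_sources(own, literature):
    """Pool own dissections with literature records; never silently merge.

    Duplicate specimen ids with identical records deduplicate to one entry;
    conflicting records for the same id raise :class:`ConflictError`.
    """
    pooled = {}
    for spec in list(own) + list(literature):
        key = (spec.taxon, spec.specimen_id)
        if key in pooled:
            if pooled[key].records != spec.records:
                raise ConflictError(
                    f"specimen {spec.specimen_id!r} of {spec.taxon!r} has "
                    f"conflicting records: {dict(pooled[key].records)!r} vs "
                    f"{dict(spec.records)!r}"
                )
            continue
        pooled[key] = spec
    return list(pooled.values())


def read_observations_csv(source: str):
    """Read specimen observations from CSV: one row per specimen x character.

    Columns: taxon, specimen_id, char_id, state (or left,right columns for
    side-specific records; empty side = unobserved).
    """
    try:
        df = pd.read_csv(io.StringIO(source), dtype=str)
    except Exception as exc:
        raise ParseError(f"observations CSV parse failed: {exc}") from exc
    needed = {"taxon", "specimen_id", "char_id"}
    if not needed <= set(df.columns):
        raise ParseError(f"observations CSV needs columns {sorted(needed)}")
    sided = {"left", "right"} <= set(df.columns)
    if not sided and "state" not in df.columns:
        raise ParseError("observations CSV needs a 'state' or 'left'/'right' columns")
    grouped = {}
    for _, row in df.iterrows():
        key = (str(row["taxon"]), str(row["specimen_id"]))
        if sided:
            left = None if pd.isna(row["left"]) else int(row["left"])
            right = None if pd.isna(row["right"]) else int(row["right"])
            obs = (left, right)
        else:
            obs = None if pd.isna(row["state"]) else int(row["state"])
        if obs is None:
            continue
        grouped.setdefault(key, {})[int(row["char_id"])] = obs
    return [
        SpecimenObservations(taxon=t, specimen_id=s, records=tuple(sorted(recs.items())))
        for (t, s), recs in grouped.items()
    ]


def code_matrix(observations, characters, unit: str = "specimen") -> CharacterMatrix:
    """Code a full CharacterMatrix from pooled specimen observations."""
    taxa = sorted({spec.taxon for spec in observations})
    columns = {}
    for c in characters:
        col = {}
        for t in taxa:
            specs = [s for s in observations if s.taxon == t]
            col[t] = code_majority(specs, c, unit=unit)
        columns[c.id] = col
    return matrix_from_columns(taxa, characters, columns)
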