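"""Hominoid muscle-character fixtures: the worked examples of the analysis.

The working topology is the seven-terminal hominoid cladogram

    (Outgroup,(Hylobatids,(Pongo,(Gorilla,((P_troglodytes,P_paniscus),Homo)))));

and the fixture matrix encodes every muscle character whose state vector is
fixed by the published comparative-dissection results: the chimpanzee-bonobo
differences (7 characters, 2 of them major), the chimpanzee-human hindlimb
differences (12, of which 7 major), the 13 major head-neck/forelimb
chimpanzee-human differences, and the individually numbered characters used
in the worked reconstruction examples (66, 83, 112, 118, 120, 131, 140).

States are 0 (ancestral condition, CS0) / 1 (derived, CS1).  Terminals not
named in a published difference list default to the ancestral state; the few
deeper-taxon states that the printed reconstructions imply (e.g. Gorilla
derived for characters 83 and 140, so the P. troglodytes change maps as an
unambiguous reversion) are set accordingly and flagged in the per-character
provenance notes.

Canonical copies ship as package data (``data/hominoid_muscles.nex`` plus
``data/hominoid_muscles_provenance.json``); a unit test asserts they agree
with the in-code table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .matrix_io import CharacterDef, CharacterMatrix, read_matrix
from .trees import PhyloTree, parse_newick

__all__ = [
    "TAXA",
    "WORKING_TOPOLOGY_NEWICK",
    "FixtureSet",
    "working_topology",
    "working_ages",
    "build_paper_fixtures",
    "fixture_nexus",
    "fixture_provenance",
]

TAXA = (
    "Outgroup",
    "Hylobatids",
    "Pongo",
    "Gorilla",
    "P_troglodytes",
    "P_paniscus",
    "Homo",
)

WORKING_TOPOLOGY_NEWICK = (
    "(Outgroup,(Hylobatids,(Pongo,(Gorilla,((P_troglodytes,P_paniscus),Homo)))));"
)

# (id, label, kind, region, states for TAXA order, provenance note)
# vector order: Outgroup, Hylobatids, Pongo, Gorilla, P_troglodytes,
#               P_paniscus, Homo
CHARACTER_TABLE = [
    (
        66,
        "intermediate tendon of omohyoideus present (CS1)",
        "minor",
        "HN",
        (0, 0, 0, 0, 1, 0, 1),
        "Bonobos have a single-bellied omohyoideus (no intermediate tendon); "
        "common chimpanzees and modern humans usually have two bellies. The "
        "single head-neck chimp-bonobo difference. With the bonobo scored "
        "ancestral it is equally parsimonious to gain the tendon on the "
        "panins+humans stem and lose it in bonobos, or to gain it "
        "independently in P. troglodytes and modern humans (2 steps).",
    ),
    (
        83,
        "pectoralis minor inserting on coracoid process (CS1)",
        "minor",
        "FL",
        (0, 0, 0, 1, 0, 1, 1),
        "Bonobos and modern humans have a pectoralis minor-coracoid "
        "attachment that common chimpanzees lack; the change maps to the "
        "P. troglodytes branch as a reversion to CS0. Gorilla is coded "
        "derived so that the reversion is unambiguous on the working "
        "topology, matching the published assignment.",
    ),
    (
        112,
        "tendon of long flexor to distal phalanx of digit 1 vestigial (CS1)",
        "minor",
        "FL",
        (0, 0, 1, 1, 1, 0, 0),
        "Bonobos have a stout flexor digitorum profundus tendon to digit 1 "
        "(ancestral); the vestigial condition is derived in common "
        "chimpanzees, gorillas and orangutans. Equally parsimonious (3 "
        "steps) to gain CS1 on the great-apes+humans stem and revert in "
        "humans and bonobos, or to gain it independently three times.",
    ),
    (
        118,
        "palmaris longus present",
        "major",
        "FL",
        (0, 0, 0, 0, 0, 0, 0),
        "Presence/absence of palmaris longus; the sample-size worked example "
        "for majority-rule coding (>20 hylobatids, 19 orangutans, 25 "
        "gorillas, 38 common chimpanzees, 11 bonobos). Constant (present) "
        "across the working taxa.",
    ),
    (
        120,
        "distinct epitrochleoanconeus absent (CS1)",
        "major",
        "FL",
        (0, 0, 1, 1, 0, 0, 1),
        "Common chimpanzees (and bonobos) have an epitrochleoanconeus that "
        "modern humans lack; one of the two Pan-clade synapomorphies, a "
        "reversion to CS0 on the Pan stem. Pongo and Gorilla are coded "
        "derived so the stem reversion is unambiguous on the working "
        "topology.",
    ),
    (
        131,
        "contrahentes digitorum to digit 4 absent (CS1)",
        "major",
        "FL",
        (0, 0, 1, 1, 0, 0, 1),
        "Common chimpanzees have contrahentes to digit 4 that modern humans "
        "lack; the second Pan-clade synapomorphy, a reversion to CS0 on the "
        "Pan stem (deep-taxon states coded as for character 120). The "
        "digit-5 contrahentes is a separate character so the 13 major "
        "head-neck/forelimb differences are counted in full.",
    ),
    (
        140,
        "intermetacarpales fused with flexores breves profundi into dorsal "
        "interossei (CS1)",
        "major",
        "FL",
        (0, 0, 0, 1, 0, 1, 1),
        "In bonobos and modern humans the intermetacarpales fuse into "
        "dorsal interossei; common chimpanzees retain separate "
        "intermetacarpales. Maps to the P. troglodytes branch as a "
        "reversion to CS0; Gorilla coded derived as for character 83. One "
        "of the two major chimp-bonobo differences.",
    ),
    # 13 major HN-FL chimp-human differences = chars 120, 131, 140 above
    # plus the ten below
    (201, "temporoparietalis present", "major", "HN", (0, 0, 0, 0, 0, 0, 1),
     "Modern humans have a temporoparietalis absent in apes; human "
     "autapomorphy, one of the 13 major head-neck/forelimb chimp-human "
     "differences."),
    (202, "risorius present", "major", "HN", (0, 0, 0, 0, 0, 0, 1),
     "Modern humans have a risorius (only a variant in chimpanzees); human "
     "autapomorphy among the 13 major head-neck/forelimb differences."),
    (203, "arytenoideus obliquus present", "major", "HN", (0, 0, 0, 0, 0, 0, 1),
     "Modern humans have an arytenoideus obliquus (only a variant in "
     "chimpanzees); human autapomorphy among the 13 major differences."),
    (204, "rhomboideus minor present", "major", "FL", (0, 0, 0, 0, 0, 0, 1),
     "Modern humans have a rhomboideus minor absent in apes; human "
     "autapomorphy among the 13 major differences."),
    (205, "flexor pollicis longus present", "major", "FL", (0, 0, 0, 0, 0, 0, 1),
     "Modern humans have a distinct flexor pollicis longus; human "
     "autapomorphy among the 13 major differences."),
    (206, "adductor pollicis accessorius present", "major", "FL",
     (0, 0, 0, 0, 0, 0, 1),
     "Modern humans have an adductor pollicis accessorius; human "
     "autapomorphy among the 13 major differences."),
    (207, "extensor pollicis brevis present", "major", "FL", (0, 0, 0, 0, 0, 0, 1),
     "Modern humans have an extensor pollicis brevis; human autapomorphy "
     "among the 13 major differences."),
    (208, "levator claviculae absent (CS1)", "major", "FL", (0, 0, 0, 0, 0, 0, 1),
     "Common chimpanzees retain a levator claviculae that modern humans "
     "have lost; among the 13 major differences."),
    (209, "dorsoepitrochlearis absent (CS1)", "major", "FL", (0, 0, 0, 0, 0, 0, 1),
     "Common chimpanzees retain a dorsoepitrochlearis that modern humans "
     "have lost; among the 13 major differences."),
    (210, "contrahentes digitorum to digit 5 absent (CS1)", "major", "FL",
     (0, 0, 0, 0, 0, 0, 1),
     "Common chimpanzees have contrahentes to digit 5 that modern humans "
     "lack; encoded separately from the digit-4 character so the printed "
     "count of 13 major head-neck/forelimb differences is met."),
    # 12 chimp-human hindlimb differences: 7 major (221-227), 5 minor
    # (228-232); all derived in the human lineage
    (221, "psoas minor absent (CS1)", "major", "HL", (0, 0, 0, 0, 0, 0, 1),
     "Psoas minor usually absent in modern humans, present in "
     "chimpanzees; one of the 7 major hindlimb chimp-human differences."),
    (222, "ischiofemoralis absent (CS1)", "major", "HL", (0, 0, 0, 0, 0, 0, 1),
     "Ischiofemoralis usually absent in modern humans; major hindlimb "
     "difference."),
    (223, "adductor minimus absent (CS1)", "major", "HL", (0, 0, 0, 0, 0, 0, 1),
     "Adductor minimus usually absent in modern humans; major hindlimb "
     "difference."),
    (224, "opponens hallucis absent (CS1)", "major", "HL", (0, 0, 0, 0, 0, 0, 1),
     "Opponens hallucis usually absent in modern humans; major hindlimb "
     "difference."),
    (225, "contrahentes pedis absent (CS1)", "major", "HL", (0, 0, 0, 0, 0, 0, 1),
     "Contrahentes pedis usually absent in modern humans; major hindlimb "
     "difference."),
    (226, "opponens digiti minimi pedis absent (CS1)", "major", "HL",
     (0, 0, 0, 0, 0, 0, 1),
     "Opponens digiti minimi of the foot usually absent in modern humans; "
     "major hindlimb difference."),
    (227, "fibularis tertius present (CS1)", "major", "HL", (0, 0, 0, 0, 0, 0, 1),
     "Modern humans have a fibularis tertius absent in chimpanzees; major "
     "hindlimb difference."),
    (228, "flexor hallucis longus tendons to digits 3-4 absent (CS1)", "minor",
     "HL", (0, 0, 0, 0, 0, 0, 1),
     "Modern humans usually lack flexor hallucis longus tendons to digits "
     "3-4; minor hindlimb difference."),
    (229, "digit 2 as interossei axis of foot (CS1)", "minor", "HL",
     (0, 0, 0, 0, 0, 0, 1),
     "In modern humans digit 2 is the interossei axis of the foot; minor "
     "hindlimb difference."),
    (230, "fibularis longus-medial cuneiform attachment present (CS1)", "minor",
     "HL", (0, 0, 0, 0, 0, 0, 1),
     "Modern humans have a fibularis longus-medial cuneiform attachment; "
     "minor hindlimb difference."),
    (231, "soleus-tibia attachment present (CS1)", "minor", "HL",
     (0, 0, 0, 0, 0, 0, 1),
     "Modern humans have a soleus attachment to the tibia; minor hindlimb "
     "difference."),
    (232, "flexor digitorum brevis-digit 5 attachment present (CS1)", "minor",
     "HL", (0, 0, 0, 0, 0, 0, 1),
     "Modern humans have a flexor digitorum brevis tendon to digit 5; "
     "minor hindlimb difference."),
    # bonobo-retained hindlimb features lost in common chimpanzees and humans
    (233, "scansorius absent (CS1)", "major", "HL", (0, 0, 0, 0, 1, 0, 1),
     "Bonobos retain a scansorius that common chimpanzees and modern "
     "humans lack; the second major chimp-bonobo difference."),
    (234, "popliteus-fibula attachment absent (CS1)", "minor", "HL",
     (0, 0, 0, 0, 1, 0, 1),
     "Bonobos retain a popliteus-fibula attachment absent in common "
     "chimpanzees and modern humans; minor chimp-bonobo difference."),
    (235, "extensor hallucis longus-proximal phalanx attachment absent (CS1)",
     "minor", "HL", (0, 0, 0, 0, 1, 0, 1),
     "Bonobos retain an extensor hallucis longus attachment to the "
     "proximal phalanx of the big toe, absent in common chimpanzees and "
     "modern humans; minor chimp-bonobo difference."),
]


@dataclass
class FixtureSet:
    tree: PhyloTree
    matrix: CharacterMatrix
    provenance: dict  # char id -> note


def working_topology() -> PhyloTree:
    """The seven-terminal hominoid working topology, outgroup-rooted."""
    return parse_newick(WORKING_TOPOLOGY_NEWICK, outgroup="Outgroup")


def working_ages(preset: str = "default") -> dict:
    """Node ages (Ma) for the working topology under a calibration preset.

    ``default``: chimpanzee-human split 8 Ma, chimpanzee-bonobo split 2 Ma;
    ``ref13``: the alternative 7.5 / 3 Ma scheme.  Deeper splits use
    conventional hominoid values; they do not enter the published rate
    arithmetic.
    """
    if preset == "default":
        hp, pan = 8.0, 2.0
    elif preset == "ref13":
        hp, pan = 7.5, 3.0
    else:
        raise ValueError(f"unknown calibration preset {preset!r}")
    return {
        frozenset(TAXA): 25.0,
        frozenset(TAXA) - {"Outgroup"}: 20.0,
        frozenset(TAXA) - {"Outgroup", "Hylobatids"}: 16.0,
        frozenset(TAXA) - {"Outgroup", "Hylobatids", "Pongo"}: 9.0,
        frozenset({"P_troglodytes", "P_paniscus", "Homo"}): hp,
        frozenset({"P_troglodytes", "P_paniscus"}): pan,
    }


def build_paper_fixtures() -> FixtureSet:
    """Working topology + fixture matrix + per-character provenance notes."""
    characters, columns, provenance = [], {}, {}
    for cid, label, kind, region, vector, note in CHARACTER_TABLE:
        c = CharacterDef(id=cid, label=label, state_labels=("0", "1"),
                         kind=kind, region=region)
        characters.append(c)
        columns[cid] = {t: frozenset([s]) for t, s in zip(TAXA, vector)}
        provenance[cid] = note
    rows = {t: tuple(columns[c.id][t] for c in characters) for t in TAXA}
    matrix = CharacterMatrix(taxa=list(TAXA), characters=characters, rows=rows)
    return FixtureSet(tree=working_topology(), matrix=matrix, provenance=provenance)


def fixture_nexus() -> str:
    """The shipped NEXUS copy of the fixture matrix."""
    return resources.files("morphoclad.data").joinpath("hominoid_muscles.nex").read_text()


def fixture_provenance() -> dict:
    """The shipped provenance notes, keyed by character id."""
    text = resources.files("morphoclad.data").joinpath(
        "hominoid_muscles_provenance.json"
    ).read_text()
    return {int(k): v for k, v in json.loads(text).items()}


def load_shipped_fixtures() -> FixtureSet:
    """FixtureSet read from the package-data NEXUS + provenance JSON."""
    matrix = read_matrix(fixture_nexus(), dialect="nexus")
    return FixtureSet(tree=working_topology(), matrix=matrix,
                      provenance=fixture_provenance())
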