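"""One-command analysis chain: search, map changes, tally differences, rate.

``run_analysis`` reproduces the full desk-scale analysis from a config:
most-parsimonious-tree search, per-branch change mapping with ambiguity and
direction, the synapomorphy table, pairwise-difference tables and the rate
table, together with a manifest (config, package version, input checksums)
that makes reruns byte-comparable.

``acceptance_suite`` evaluates a finished report bundle against the
published desk-scale quantities; checks that need the full supplementary
character matrix are reported ``not-evaluable`` (not failed) when the run
used fixtures only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .fixtures import TAXA, working_ages
from .matrix_io import read_matrix, validate_matrix
from .parsimony import branch_and_bound_search, ensemble_indices
from .rates import RateTable, branch_rate_table, divergence_rate, format_rate, pairwise_differences
from .reconstruction import map_branch_changes, summarize_synapomorphies, branch_name
from .trees import parse_newick, write_newick

log = logging.getLogger("morphoclad")

__all__ = ["RunConfig", "run_analysis", "acceptance_suite"]


@dataclass
class RunConfig:
    matrix_path: str
    outgroup: str
    tree_path: str = None  # reporting topology; first MPT when absent
    calibration: str = "default"
    policy: str = "deltran"
    out_dir: str = None
    seed: int = 0
    log_level: str = "INFO"
    #: set when the matrix is the complete character set rather than the
    #: printed-fixture subset; gates the full-matrix acceptance checks
    full_matrix: bool = False

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the bundle."""
    logging.basicConfig(level=config.log_level)
    stage = "read-inputs"
    try:
        matrix_path = Path(config.matrix_path)
        source = matrix_path.read_text()
        dialect = "csv" if matrix_path.suffix.lower() == ".csv" else "nexus"
        matrix = read_matrix(source, dialect=dialect)
        problems = validate_matrix(matrix)
        if problems:
            raise ValueError("; ".join(problems))
        checksums = {str(matrix_path): _sha256(matrix_path)}
        given_tree = None
        if config.tree_path:
            tree_path = Path(config.tree_path)
            given_tree = parse_newick(tree_path.read_text(), outgroup=config.outgroup)
            checksums[str(tree_path)] = _sha256(tree_path)

        stage = "search"
        log.info("branch-and-bound search over %d taxa", len(matrix.taxa))
        mpts, score = branch_and_bound_search(matrix, outgroup=config.outgroup)

        stage = "map-changes"
        report_tree = given_tree if given_tree is not None else mpts[0]
        report_score = ensemble_indices(report_tree, matrix)
        cmap = map_branch_changes(report_tree, matrix, policy=config.policy)
        synapo = summarize_synapomorphies(report_tree, matrix)

        stage = "pairwise"
        pairwise = {}
        taxa = matrix.taxa
        for i, a in enumerate(taxa):
            for b in taxa[i + 1:]:
                n_all, _ = pairwise_differences(matrix, a, b)
                n_major, _ = pairwise_differences(matrix, a, b, major_only=True)
                by_region = {}
                for region in ("HN", "FL", "HL", "trunk"):
                    n_r, _ = pairwise_differences(matrix, a, b, regions=[region])
                    by_region[region] = n_r
                pairwise[f"{a}|{b}"] = {
                    "all": n_all,
                    "major": n_major,
                    "by_region": by_region,
                }

        stage = "rates"
        rates = RateTable()
        if set(matrix.taxa) == set(TAXA) and set(report_tree.leaf_labels()) == set(TAXA):
            aged = report_tree.copy().set_ages(working_ages(config.calibration))
            counts = {}
            for r in cmap.records:
                counts[r.child_clade] = counts.get(r.child_clade, 0) + 1
            rates = branch_rate_table(aged, counts)

        stage = "assemble"
        bundle = {
            "search": {
                "n_mpts": len(mpts),
                "trees": [write_newick(t) for t in mpts],
                "score": score.as_dict(),
            },
            "tree": write_newick(report_tree),
            "reporting_score": report_score.as_dict(),
            "mpr_counts": {str(k): v for k, v in cmap.mpr_counts.items()},
            "changes": [
                {
                    "char_id": r.char_id,
                    "branch": r.branch,
                    "from": r.from_state,
                    "to": r.to_state,
                    "direction": r.direction,
                    "ambiguous": r.ambiguous,
                }
                for r in cmap.records
            ],
            "synapomorphies": {
                branch_name(clade): {
                    "unambiguous": sorted(
                        {r.char_id for r in entry["unambiguous"]}
                    ),
                    "unambiguous_directions": {
                        str(r.char_id): r.direction for r in entry["unambiguous"]
                    },
                    "ambiguous": sorted({d["char_id"] for d in entry["ambiguous"]}),
                }
                for clade, entry in synapo.items()
            },
            "pairwise": pairwise,
            "rates": rates.as_records(),
            "manifest": {
                "config": asdict(config),
                "version": __version__,
                "checksums": checksums,
            },
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
        (out / "mpts.nwk").write_text("\n".join(bundle["search"]["trees"]) + "\n")
        tsv = ["char_id\tbranch\tfrom\tto\tdirection\tambiguous"]
        for r in bundle["changes"]:
            tsv.append(
                f"{r['char_id']}\t{r['branch']}\t{r['from']}\t{r['to']}"
                f"\t{r['direction']}\t{r['ambiguous']}"
            )
        (out / "changes.tsv").write_text("\n".join(tsv) + "\n")
    return bundle


# -- acceptance -------------------------------------------------------------

_PAN_STEM = branch_name(frozenset({"P_troglodytes", "P_paniscus"}))


def _row(check, computed, expected, verdict=None):
    if verdict is None:
        verdict = "pass" if computed == expected else "fail"
    return {"check": check, "computed": computed, "expected": expected,
            "verdict": verdict}


def acceptance_suite(bundle: dict) -> list:
    """Evaluate a report bundle against the published desk-scale quantities.

    Returns one row per check: computed value, expected value, verdict
    (``pass`` / ``fail`` / ``not-evaluable``).  Full-matrix checks (single
    most-parsimonious tree with L = 303, CI = 57, RI = 75) are evaluated
    only when the run declared a complete character matrix.
    """
    rows = []
    steps = bundle.get("reporting_score", {}).get("per_character_steps", {})
    mprs = bundle.get("mpr_counts", {})

    def maybe(check, computed, expected):
        if computed is None:
            rows.append(_row(check, None, expected, "not-evaluable"))
        else:
            rows.append(_row(check, computed, expected))

    maybe("char112_steps", steps.get("112"), 3)
    maybe("char66_steps", steps.get("66"), 2)
    if "112" in mprs:
        rows.append(_row("char112_equal_parsimony", mprs["112"] >= 2, True))
    else:
        rows.append(_row("char112_equal_parsimony", None, True, "not-evaluable"))
    maybe("char66_mpr_count", mprs.get("66"), 2)

    pairwise = bundle.get("pairwise", {})

    def pair(a, b):
        return pairwise.get(f"{a}|{b}") or pairwise.get(f"{b}|{a}")

    pan = pair("P_troglodytes", "P_paniscus")
    ch = pair("P_troglodytes", "Homo")
    maybe("chimp_bonobo_differences", pan and pan["all"], 7)
    maybe("chimp_bonobo_major_differences", pan and pan["major"], 2)
    maybe("chimp_human_hindlimb_differences", ch and ch["by_region"]["HL"], 12)
    maybe("chimp_human_major_differences", ch and ch["major"], 20)

    # published rate arithmetic: printed change counts over split spans
    rows.append(_row("rate_chimp_human_per_ma", divergence_rate(28, 8.0), 3.5))
    rows.append(_row("rate_human_clade_per_ma", divergence_rate(4, 8.0), 0.5))
    rows.append(_row("rate_gorilla_genus_display", format_rate(divergence_rate(2, 7.1)), "0.28"))

    synapo = bundle.get("synapomorphies", {})
    stem = synapo.get(_PAN_STEM)
    if stem is None:
        rows.append(_row("pan_stem_synapomorphies", None, [120, 131], "not-evaluable"))
        rows.append(_row("pan_stem_all_reversions", None, True, "not-evaluable"))
    else:
        rows.append(_row("pan_stem_synapomorphies", stem["unambiguous"], [120, 131]))
        rows.append(
            _row(
                "pan_stem_all_reversions",
                all(d == "reversion" for d in stem["unambiguous_directions"].values()),
                True,
            )
        )
    changes = bundle.get("changes")
    if changes is None:
        rows.append(_row("p_troglodytes_reversions_83_140", None, True, "not-evaluable"))
        rows.append(_row("p_paniscus_changes", None, 0, "not-evaluable"))
    else:
        pt = [c for c in changes if c["branch"] == "P_troglodytes"]
        pt_rev = {
            c["char_id"] for c in pt if c["direction"] == "reversion"
        }
        rows.append(_row("p_troglodytes_reversions_83_140", {83, 140} <= pt_rev, True))
        pp = [c for c in changes if c["branch"] == "P_paniscus"]
        rows.append(_row("p_paniscus_changes", len(pp), 0))

    full = bundle.get("manifest", {}).get("config", {}).get("full_matrix", False)
    score = bundle.get("search", {}).get("score", {})
    full_checks = [
        ("full_matrix_single_mpt", bundle.get("search", {}).get("n_mpts"), 1),
        ("full_matrix_length", score.get("length"), 303),
        ("full_matrix_ci_percent", score.get("ci_percent"), 57),
        ("full_matrix_ri_percent", score.get("ri_percent"), 75),
    ]
    for check, computed, expected in full_checks:
        if not full or computed is None:
            rows.append(_row(check, None, expected, "not-evaluable"))
        else:
            rows.append(_row(check, computed, expected))
    return rows
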