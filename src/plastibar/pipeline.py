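"""End-to-end orchestration: structure -> scan -> mine -> discriminate.

``run_pipeline`` consumes a set of circular genomes (optional), an aligned
FASTA and a groups TSV, runs every stage with the configured parameters,
and writes a machine-readable JSON report plus per-stage TSVs.  The report
is regenerable byte-identically from the same inputs, configuration and
seed (no timestamps inside).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

from . import __version__
from .barcode import BarcodeScanParams, scan_candidates
from .discriminate import evaluate_discrimination
from .structure import read_genomes, structure_table
from .variation import (
    AlignedMatrix,
    GroupAssignment,
    count_site_classes,
    sliding_window_diversity,
)

__all__ = ["RunConfig", "run_pipeline", "compare_barcode_panels", "validate_report"]


@dataclass
class RunConfig:
    alignment: str
    groups: str
    genomes: Optional[str] = None
    out_dir: str = "plastibar_out"
    window: int = 800
    step: int = 200
    deletion: str = "complete"
    min_ir: int = 1000
    max_ir_mismatch: int = 0
    scan: BarcodeScanParams = field(default_factory=BarcodeScanParams)
    model: str = "JC69"
    bootstrap: int = 1000
    threshold: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if self.window < self.step:
            raise ValueError("window must be >= step")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.bootstrap < 1:
            raise ValueError("bootstrap must be >= 1")
        if self.scan.max_len < 1 or self.scan.step < 1:
            raise ValueError("scan parameters must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _tsv(path: str, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join("" if v is None else str(v) for v in r) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report dict (also written to disk)."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {
        "tool": "plastibar",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "stages": {},
    }

    # stage: structure
    if config.genomes:
        try:
            genomes = read_genomes(config.genomes)
            rows = structure_table(
                genomes, min_len=config.min_ir, max_mismatch=config.max_ir_mismatch
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"[structure] {exc}") from exc
        report["stages"]["structure"] = {"genomes": rows}
        _tsv(
            os.path.join(config.out_dir, "structure.tsv"),
            ["id", "length", "gc_percent", "lsc", "ssc", "ir", "rotation_offset"],
            [
                [r["id"], r["length"], r["gc_percent"], r["lsc"], r["ssc"], r["ir"], r["rotation_offset"]]
                for r in rows
            ],
        )

    # stage: scan
    try:
        aln = AlignedMatrix.from_fasta(config.alignment)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[scan] cannot read alignment: {exc}") from exc
    groups = GroupAssignment.from_tsv(config.groups)
    groups.validate_against(aln)
    ingroup = [s for s in aln.sample_ids if s not in groups.outgroups]
    sub = aln.subset_samples(ingroup)
    track = sliding_window_diversity(
        sub, window_len=config.window, step=config.step, deletion=config.deletion
    )
    site_summary = count_site_classes(sub)
    report["stages"]["scan"] = {
        "alignment_length": aln.n_cols,
        "n_samples": aln.n_samples,
        "site_classes": {
            "variable": site_summary.n_variable,
            "parsimony_informative": site_summary.n_parsimony_informative,
            "singleton": site_summary.n_singleton,
            "excluded": site_summary.n_excluded,
        },
        "windows": [
            {
                "start": w.start,
                "end": w.end,
                "pi": w.pi,
                "usable_sites": w.usable_sites,
                "truncated": w.truncated,
            }
            for w in track
        ],
    }
    _tsv(
        os.path.join(config.out_dir, "windows.tsv"),
        ["start_1based", "end_1based", "usable_sites", "pi"],
        [
            [w.start + 1, w.end, w.usable_sites, "" if w.pi is None else f"{w.pi:.6f}"]
            for w in track
        ],
    )

    # stage: mine
    candidates, tally = scan_candidates(aln, groups, config.scan)
    report["stages"]["mine"] = {
        "rejection_tally": tally,
        "candidates": [
            {
                "core": list(c.core),
                "length": c.length,
                "n_variable": c.summary.n_variable,
                "n_parsimony_informative": c.summary.n_parsimony_informative,
                "diagnostic_coverage": c.diagnostic_coverage,
                "pi": c.pi,
                "gap_fraction": c.gap_fraction,
                "rank_score": c.rank_score,
            }
            for c in candidates
        ],
    }
    with open(os.path.join(config.out_dir, "candidates.bed"), "w") as fh:
        for c in candidates:
            fh.write(f"alignment\t{c.core[0]}\t{c.core[1]}\tcandidate\t{c.rank_score:.0f}\t+\n")
    _tsv(
        os.path.join(config.out_dir, "candidates.tsv"),
        ["start_1based", "end_1based", "length", "variable", "parsimony_informative", "pi"]
        + [f"diag_{g}" for g in groups.ingroup_labels()],
        [
            [
                c.core[0] + 1,
                c.core[1],
                c.length,
                c.summary.n_variable,
                c.summary.n_parsimony_informative,
                "" if c.pi is None else f"{c.pi:.6f}",
            ]
            + [c.diagnostic_coverage.get(g, 0) for g in groups.ingroup_labels()]
            for c in candidates
        ],
    )

    # stage: discriminate (per candidate region)
    disc_rows = []
    disc_report = []
    for k, cand in enumerate(candidates, start=1):
        region = aln.slice_columns(*cand.core)
        result = evaluate_discrimination(
            region,
            groups,
            model=config.model,
            B=config.bootstrap,
            seed=config.seed + k,
            threshold=config.threshold,
        )
        entry = {
            "region": f"candidate_{k}",
            "core": list(cand.core),
            "all_multisample_groups_succeed": result.all_success,
            "groups": {
                g: {
                    "n": v.n_samples,
                    "monophyletic": v.monophyletic,
                    "support": v.support,
                    "success": v.success,
                }
                for g, v in result.verdicts.items()
            },
            "tree_newick": result.tree_newick,
        }
        disc_report.append(entry)
        for g, v in result.verdicts.items():
            disc_rows.append(
                [f"candidate_{k}", g, v.n_samples, v.monophyletic, v.support, v.success]
            )
    report["stages"]["discriminate"] = {"regions": disc_report}
    _tsv(
        os.path.join(config.out_dir, "discrimination.tsv"),
        ["region", "group", "n", "monophyletic", "support", "success"],
        disc_rows,
    )

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


_REPORT_SCHEMA_PATH = os.path.join(os.path.dirname(__file__), "report_schema.json")


def validate_report(report: dict) -> list[str]:
    """Check the report against the published schema (schema kept minimal:
    required keys and value types).  Returns a list of problems, empty when
    valid."""
    with open(_REPORT_SCHEMA_PATH) as fh:
        schema = json.load(fh)
    problems: list[str] = []

    def check(node: dict, spec: dict, path: str) -> None:
        for key, kind in spec.get("required", {}).items():
            if key not in node:
                problems.append(f"{path}: missing {key}")
                continue
            val = node[key]
            expected = {
                "object": dict,
                "array": list,
                "string": str,
                "number": (int, float),
            }[kind if isinstance(kind, str) else kind["type"]]
            if not isinstance(val, expected):
                problems.append(f"{path}.{key}: expected {kind}")
            if isinstance(kind, dict) and isinstance(val, dict):
                check(val, kind, f"{path}.{key}")

    check(report, schema, "report")
    return problems


def compare_barcode_panels(
    report: dict, panel_a: list[str], panel_b: list[str]
) -> dict:
    """Per-panel totals (length, variable, PI, success counts) and deltas."""
    if not panel_a or not panel_b:
        raise ValueError("panels must be non-empty")
    regions = {r["region"]: r for r in report["stages"]["discriminate"]["regions"]}
    cands = {
        f"candidate_{k}": c
        for k, c in enumerate(report["stages"]["mine"]["candidates"], start=1)
    }

    def totals(panel: list[str]) -> dict:
        missing = [p for p in panel if p not in cands]
        if missing:
            raise ValueError(f"unknown regions: {missing}")
        t = {"length": 0, "variable": 0, "parsimony_informative": 0, "success_groups": 0}
        for p in panel:
            c = cands[p]
            t["length"] += c["length"]
            t["variable"] += c["n_variable"]
            t["parsimony_informative"] += c["n_parsimony_informative"]
            if p in regions:
                t["success_groups"] += sum(
                    1 for g in regions[p]["groups"].values() if g["success"]
                )
        return t

    ta, tb = totals(panel_a), totals(panel_b)
    return {
        "panel_a": ta,
        "panel_b": tb,
        "delta": {k: ta[k] - tb[k] for k in ta},
    }
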