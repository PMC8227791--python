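"""End-to-end orchestration: enumerate -> score -> summarize -> compare -> scan.

A :class:`RunConfig` fully determines a run; it is serialized into the
result directory so any output can be traced back to its inputs.  Data
goes to files, logging to stderr, and two runs with the same config and
seed produce byte-identical primary outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from hexamask.affinity_model import (
    ScoreModelParams,
    ScoreTable,
    load_score_table,
    save_score_table,
    simulate_scores,
)
from hexamask.duplex_space import enumerate_duplexes, mask_of
from hexamask.mask_aggregation import (
    best_complex,
    coincidence_probability,
    compare_peptides,
    format_probability,
    summarize_by_mask,
    write_summary_table,
)
from hexamask.promoter_scan import (
    Needle,
    ScanPolicy,
    read_promoters,
    scan,
    write_occurrence_report,
)

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger("hexamask")


@dataclass
class PeptideSpec:
    """One peptide's score source: a file of docking output or a simulation."""

    label: str
    source: str = "simulate"  # "simulate" | "file"
    path: str | None = None
    beta0: float = -31.76
    beta_gc: float = -0.925
    sigma: float = 2.5

    def __post_init__(self) -> None:
        if self.source not in ("simulate", "file"):
            raise ValueError(f"source must be 'simulate' or 'file', got {self.source!r}")
        if self.source == "file" and not self.path:
            raise ValueError(f"peptide {self.label}: source 'file' requires a path")


@dataclass
class RunConfig:
    """Everything a full run needs; validated up front, serialized out."""

    k: int = 6
    peptides: list[PeptideSpec] = field(default_factory=list)
    keying: str = "canonical"
    promoters_fasta: str | None = None
    needles: list[tuple[str, str, str]] = field(default_factory=list)  # (label, kind, pattern)
    overlapping: bool = True
    biological_strands_only: bool = False
    seed: int = 0
    out_dir: str = "hexamask_run"

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not self.peptides:
            raise ValueError("at least one peptide must be configured")
        if self.keying not in ("canonical", "as_written"):
            raise ValueError(f"unknown keying policy {self.keying!r}")
        for pep in self.peptides:
            if pep.source == "file" and not Path(pep.path).exists():
                raise FileNotFoundError(f"score table not found: {pep.path}")
        if self.promoters_fasta and not Path(self.promoters_fasta).exists():
            raise FileNotFoundError(f"promoter FASTA not found: {self.promoters_fasta}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.to_json().encode()).hexdigest()[:12]


def run_all(config: RunConfig) -> Path:
    """Execute every stage and write the result directory.

    Stages: enumerate the duplex space; obtain one score table per
    peptide (simulate or load); summarize each by mask; compare the
    first two peptides; scan promoters for the configured needles (or,
    by default, each peptide's best-complex sequence and mask).  Stage
    errors propagate with the stage named.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json() + "\n")
    log: dict = {"config_hash": _config_hash(config), "stages": {}}

    # enumerate
    logger.info("enumerating duplex space k=%d", config.k)
    duplexes = enumerate_duplexes(config.k)
    enum_dir = out / "enumerate"
    enum_dir.mkdir(exist_ok=True)
    with (enum_dir / "duplexes.tsv").open("w") as fh:
        fh.write("canonical\tmask\n")
        for d in duplexes:
            fh.write(f"{d.canonical}\t{d.mask}\n")
    log["stages"]["enumerate"] = {"n_duplexes": len(duplexes)}

    # score + summarize
    tables: dict[str, ScoreTable] = {}
    summaries = {}
    score_dir = out / "scores"
    score_dir.mkdir(exist_ok=True)
    for i, pep in enumerate(config.peptides):
        if pep.source == "file":
            table = load_score_table(pep.path, peptide_id=pep.label)
        else:
            params = ScoreModelParams(
                beta0=pep.beta0, beta_gc=pep.beta_gc, sigma=pep.sigma,
                seed=config.seed + i,
            )
            table = simulate_scores(params, duplexes, peptide_id=pep.label)
            save_score_table(table, score_dir / f"scores_{pep.label}.tsv")
        tables[pep.label] = table
        summary = summarize_by_mask(table, keying=config.keying)
        summaries[pep.label] = summary
        write_summary_table(summary, score_dir / f"summary_{pep.label}.tsv")
        log["stages"].setdefault("score", {})[pep.label] = {
            "n_records": len(table),
            "complete": table.is_complete,
            "n_masks": len(summary),
        }

    # compare + coincidence
    report: dict = {
        "coincidence_probability": coincidence_probability(config.k),
        "coincidence_probability_display": format_probability(
            coincidence_probability(config.k)
        ),
        "best_complexes": {},
    }
    for label, summary in summaries.items():
        seq, score, mask = best_complex(summary)
        report["best_complexes"][label] = {
            "sequence": seq, "score": score, "mask": mask,
        }
    if len(config.peptides) >= 2:
        a, b = config.peptides[0].label, config.peptides[1].label
        cmp = compare_peptides(summaries[a], summaries[b])
        report["comparison"] = {
            "peptides": [a, b],
            "shared_masks": cmp.shared_masks,
            "best_masks_identical": cmp.best_masks_identical,
            "best_sequences": list(cmp.best_sequences),
            "n_masks_a_lower": sum(1 for _, d in cmp.mean_differences if d < 0),
        }
    (out / "comparison.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )

    # scan
    if config.promoters_fasta:
        promoters = read_promoters(config.promoters_fasta)
        if config.needles:
            needles = [
                Needle(kind=kind, pattern=pattern, label=label)
                for label, kind, pattern in config.needles
            ]
        else:
            needles = []
            for label, summary in summaries.items():
                seq, _, mask = best_complex(summary)
                needles.append(Needle(kind="exact", pattern=seq, label=f"{label}:best"))
                needles.append(Needle(kind="mask", pattern=mask, label=f"{label}:mask"))
            # dedup identical patterns under different peptides
            uniq = {}
            for n in needles:
                uniq.setdefault((n.kind, n.pattern), n)
            needles = list(uniq.values())
        policy = ScanPolicy(
            overlapping=config.overlapping,
            biological_strands_only=config.biological_strands_only,
        )
        occ = scan(needles, promoters, policy)
        scan_dir = out / "scan"
        scan_dir.mkdir(exist_ok=True)
        write_occurrence_report(occ, scan_dir / "occurrences.tsv")
        (scan_dir / "occurrences.json").write_text(occ.to_json() + "\n")
        log["stages"]["scan"] = {
            "n_promoters": len(promoters),
            "n_needles": len(needles),
        }

    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    logger.info("run complete: %s", out)
    return out


def setup_logging(verbosity: int = 1) -> None:
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    logging.basicConfig(stream=sys.stderr, level=level, format="%(name)s: %(message)s")
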