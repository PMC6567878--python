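"""End-to-end scan pipeline: read inputs, scan, select, write reports.

A run writes into its output directory:

* ``scan_report.tsv`` — one full-precision row per tested family;
* ``candidates.tsv`` — the selected candidates with provenance;
* ``scan_table.txt`` — the rendered fixed-width table (2-decimal medians,
  4-decimal p-values);
* ``run_config.yaml`` — the effective configuration of the run;
* ``run.log`` — every excluded gene/family with a machine-parsable reason code.

Report files contain no timestamps, so identical inputs and configuration
produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import yaml

from . import enrichment, io, selection
from .errors import MirenrichError
from .report import render_table

logger = logging.getLogger("mirenrich")


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of one scan-pipeline run."""

    fc_path: str
    targets_path: str
    members_path: str
    cargo_path: str
    out_dir: str
    alternative: str = "two-sided"
    exact_limit: int = 16
    min_targets: int = 5
    prefilter: str = "none"
    alpha: float = 0.05
    correction: str = "none"
    top_k: int = 50
    force_include: Tuple[str, ...] = ()
    duplicate_policy: str = "error"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["force_include"] = list(self.force_include)
        return d


@dataclass(frozen=True)
class PipelineOutput:
    results: List[enrichment.FamilyEnrichmentResult]
    candidates: List[selection.CandidateSelection]
    paths: dict


def _attach_run_log(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    handler.setLevel(logging.INFO)
    root = logging.getLogger("mirenrich")
    prev_level = root.level
    root.addHandler(handler)
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)
    handler._prev_level = prev_level  # restored on detach
    return handler


def _detach_run_log(handler: logging.Handler) -> None:
    root = logging.getLogger("mirenrich")
    root.removeHandler(handler)
    root.setLevel(handler._prev_level)
    handler.close()


def run_scan_pipeline(config: RunConfig) -> PipelineOutput:
    """Run scan → significance filter → cargo cross-match → forced includes.

    Raises a typed :class:`~mirenrich.errors.MirenrichError` subclass on any
    input, configuration, or empty-result failure; the CLI maps these to
    exit codes.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _attach_run_log(out_dir)
    try:
        fc = io.read_fold_change_table(config.fc_path,
                                       duplicate_policy=config.duplicate_policy)
        predictions = io.read_target_predictions(config.targets_path, config.members_path)
        cargo = io.read_cargo_profile(config.cargo_path)

        results = enrichment.scan_families(
            fc, predictions,
            alternative=config.alternative,
            exact_limit=config.exact_limit,
            min_targets=config.min_targets,
            prefilter=config.prefilter,
        )
        significant = selection.significant_families(
            results, alpha=config.alpha, correction=config.correction)
        candidates = selection.crossmatch_cargo(
            significant, predictions, cargo, top_k=config.top_k)
        candidates = selection.apply_forced_includes(
            candidates, config.force_include, cargo)

        sel_info = {c.family_id: (c.ev_rank, True) for c in candidates
                    if c.provenance == "scan+cargo"}
        paths = {
            "scan_report": out_dir / "scan_report.tsv",
            "candidates": out_dir / "candidates.tsv",
            "table": out_dir / "scan_table.txt",
            "config": out_dir / "run_config.yaml",
            "log": out_dir / "run.log",
        }
        io.write_scan_report(results, paths["scan_report"], selection_info=sel_info)
        selection.write_candidate_report(candidates, paths["candidates"])
        ev_ranks = {fam: rank for fam, (rank, sel) in sel_info.items() if rank is not None}
        paths["table"].write_text(render_table(results, ev_ranks), encoding="utf-8")
        with open(paths["config"], "w", encoding="utf-8") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        logger.info("PIPELINE_OK families_tested=%d candidates=%d",
                    len(results), len(candidates))
        return PipelineOutput(results=results, candidates=candidates,
                              paths={k: str(v) for k, v in paths.items()})
    finally:
        _detach_run_log(handler)
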