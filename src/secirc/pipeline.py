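"""End-to-end orchestration: SE calling -> association -> specificity ->
candidate funnel -> seed scan, with a machine-readable run report.

The run is fully deterministic given its configuration; the only random
number generator in the package lives in :mod:`secirc.synthetic_data`.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .candidate_selection import (
    DEFAULT_FC_THRESHOLD,
    DEFAULT_PSEUDOCOUNT,
    fold_change_filter,
    conservation_filter,
    select_candidates,
    write_candidates,
)
from .circ_association import (
    DEFAULT_ASSIGNMENT_WINDOW,
    SE_LABEL,
    assign_enhancers,
    circs_from_bed,
    classify_circs,
    write_classes,
)
from .io_formats import (
    read_bed,
    read_expression_matrix,
    read_fasta,
    read_ortholog_table,
    write_json,
)
from .se_calling import DEFAULT_STITCH_WINDOW, SEParams, call_superenhancers
from .seed_scan import scan_all_seed_sites, write_sites
from .specificity import DEFAULT_TAU, specificity_report, tissue_specificity_scores

logger = logging.getLogger("secirc")


@dataclass
class RunConfig:
    """All inputs and stage parameters of one pipeline run."""

    peaks: str
    circs: str
    expression: str
    orthologs: str
    circ_fasta: str | None = None
    mirna_fasta: str | None = None
    control: str | None = None
    out_dir: str = "secirc_out"
    stitch_window: int = DEFAULT_STITCH_WINDOW
    tss_exclusion: int = 0
    assignment_window: int = DEFAULT_ASSIGNMENT_WINDOW
    tau: float = DEFAULT_TAU
    fc_threshold: float = DEFAULT_FC_THRESHOLD
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    stage_pair: tuple[str, str] | None = None  # default: matrix column order

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        if cfg.stage_pair is not None:
            cfg.stage_pair = tuple(cfg.stage_pair)  # type: ignore[assignment]
        return cfg

    def validate(self) -> None:
        for name in ("peaks", "circs", "expression", "orthologs"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} input missing: {p}")
        for name in ("circ_fasta", "mirna_fasta", "control"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input missing: {p}")
        if not 0 <= self.tau <= 1:
            raise ValueError("tau must be in [0, 1]")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")


@dataclass
class RunReport:
    counts: dict[str, int] = field(default_factory=dict)
    cutoff_score: float | None = None
    seconds_per_stage: dict[str, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self) -> dict:
        return {
            "counts": self.counts,
            "cutoff_score": self.cutoff_score,
            "seconds_per_stage": {k: round(v, 3) for k, v in self.seconds_per_stage.items()},
            "config": self.config,
            "version": self.version,
        }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order; any failure aborts with its stage name."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={k: getattr(config, k) for k in config.__dataclass_fields__})
    t_all = time.perf_counter()

    def stage(name: str):
        logger.info("stage %s", name)
        return _StageTimer(name, report)

    try:
        with stage("se_call"):
            peaks = read_bed(config.peaks)
            signal = {p.id: p.signal if p.signal is not None else 0.0 for p in peaks}
            control = None
            if config.control:
                control = {p.id: p.signal or 0.0 for p in read_bed(config.control)}
            calls = call_superenhancers(
                peaks,
                signal,
                control,
                SEParams(config.stitch_window, config.tss_exclusion),
                out_dir=out,
            )
            report.counts["peaks"] = len(peaks)
            report.counts["stitched_regions"] = len(calls)
            report.counts["superenhancers"] = sum(c.is_super for c in calls)
            report.cutoff_score = calls[0].cutoff_score if calls else None

        with stage("associate"):
            circs = circs_from_bed(read_bed(config.circs))
            assignments = assign_enhancers(calls, circs, config.assignment_window)
            classes = classify_circs(assignments, circs)
            write_classes(classes, out / "classes.tsv")
            report.counts["circRNAs"] = len(circs)
            report.counts["se_circRNAs"] = sum(c.label == SE_LABEL for c in classes)

        with stage("specificity"):
            matrix = read_expression_matrix(config.expression)
            spec = specificity_report(matrix, classes, config.tau)
            write_json(spec, out / "specificity_report.json")

        with stage("candidates"):
            stages = config.stage_pair or tuple(matrix.stages[:2])
            de_calls = fold_change_filter(
                matrix, stages, config.fc_threshold, config.pseudocount
            )
            orthologs = read_ortholog_table(config.orthologs)
            conserved = conservation_filter(matrix.circ_ids, orthologs)
            scores = {
                cid: s.score for cid, s in tissue_specificity_scores(matrix).items()
            }
            candidates = select_candidates(classes, de_calls, conserved, scores, orthologs)
            write_candidates(candidates, out / "candidates.tsv")
            report.counts["de_circRNAs"] = sum(d.is_de for d in de_calls)
            report.counts["conserved_circRNAs"] = len(conserved)
            report.counts["candidates"] = len(candidates)

        if config.circ_fasta and config.mirna_fasta:
            with stage("scan"):
                circ_seqs = read_fasta(config.circ_fasta)
                mirna_seqs = read_fasta(config.mirna_fasta)
                sites = scan_all_seed_sites(circ_seqs, mirna_seqs)
                write_sites(sites, out / "sites.tsv")
                report.counts["seed_sites"] = len(sites)
    except Exception as exc:
        failed = next(reversed(report.seconds_per_stage)) if report.seconds_per_stage else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    report.seconds_per_stage["total"] = time.perf_counter() - t_all
    write_json(report.to_json(), out / "report.json")
    return report


class _StageTimer:
    def __init__(self, name: str, report: RunReport):
        self.name = name
        self.report = report

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.report.seconds_per_stage[self.name] = time.perf_counter() - self.t0
        if exc is not None:
            logger.error("stage %s failed: %s", self.name, exc)
        return False
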