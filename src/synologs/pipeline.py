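"""End-to-end orchestration: simulate/load -> detect -> summarize -> context.

Single-process and per-genome: each run handles one genome and writes a
deterministic artifact bundle (groups TSV, per-genome summary TSV, cohort
JSON, context TSV, config echo log).  Multi-genome cohorts are assembled
from directories of per-genome summary files, so no shared memory is
needed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from . import io as sio
from .context import call_contexts
from .detect import (
    all_pair_hits,
    apply_category_filter,
    build_groups,
    candidate_pairs,
    filter_truncated,
)
from .records import DetectionConfig, GenomeSynologSummary, ProteinRecord, SynologGroup
from .simulate import SyntheticDesign, generate_genome
from .stats import cohort_summarize, summarize_genome


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one pipeline run needs, defaults materialized."""

    out_dir: Path
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    design: Optional[SyntheticDesign] = None
    fasta: Optional[Path] = None
    annotations: Optional[Path] = None
    window: int = 5
    share_decimals: int = 1

    def resolved(self) -> Dict:
        d = {
            "out_dir": str(self.out_dir),
            "fasta": None if self.fasta is None else str(self.fasta),
            "annotations": None
            if self.annotations is None
            else str(self.annotations),
            "window": self.window,
            "share_decimals": self.share_decimals,
        }
        for k, v in dataclasses.asdict(self.detection).items():
            d[f"detection.{k}"] = v
        if self.design is not None:
            for k, v in dataclasses.asdict(self.design).items():
                d[f"design.{k}"] = v
        return d


@dataclass
class RunResult:
    records: List[ProteinRecord]
    groups: List[SynologGroup]
    truncated: List[str]
    summary: GenomeSynologSummary
    paths: Dict[str, Path]


def detect_genome(
    records: Sequence[ProteinRecord], config: DetectionConfig
) -> tuple:
    """Detection plus summary bookkeeping for one genome.

    Returns (groups, truncated gene ids, summary).  The summary always
    carries the number of groups at the 0.90 identity cutoff: for a
    detection already run at a cutoff this equals the group count, while a
    family-mode run without a cutoff re-partitions its evaluated pairs at
    0.90 without re-aligning.
    """
    in_scope = apply_category_filter(records, config)
    if not in_scope:
        raise ValueError("no records in scope after category filter")
    kept, flagged = filter_truncated(in_scope, config)
    hits = all_pair_hits(kept, config)
    passing = candidate_pairs(kept, config, hits=hits)
    groups = build_groups(passing, kept, all_hits=hits)
    if config.identity_threshold is not None:
        n_at_cutoff = len(groups)
    else:
        cutoff_cfg = dataclasses.replace(config, identity_threshold=0.90)
        cut_pairs = candidate_pairs(kept, cutoff_cfg, hits=hits)
        n_at_cutoff = len(build_groups(cut_pairs, kept, all_hits=hits))
    summary = summarize_genome(
        groups,
        kept,
        n_groups_at_cutoff=n_at_cutoff,
        n_proteins_total=len(records),
    )
    return groups, flagged, summary


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages and write the artifact bundle under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "log": out / "run.log",
        "fasta": out / "proteome.fasta",
        "annotations": out / "annotations.tsv",
        "truth": out / "truth.tsv",
        "groups": out / "groups.tsv",
        "summary": out / "summary.tsv",
        "cohort": out / "cohort.json",
        "context": out / "context.tsv",
    }
    sio.write_run_log(paths["log"], config.resolved(), header="synologs run")

    try:
        if config.design is not None:
            records, truth = generate_genome(config.design)
            sio.write_proteome(records, paths["fasta"], paths["annotations"])
            sio.write_truth(truth, paths["truth"])
        else:
            if config.fasta is None or config.annotations is None:
                raise ValueError("need either a design or fasta + annotations")
            records = sio.read_proteome(config.fasta, config.annotations)
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise StageError("io_formats", exc) from exc

    try:
        groups, flagged, summary = detect_genome(records, config.detection)
        sio.write_groups(groups, paths["groups"])
        sio.write_summaries([summary], paths["summary"])
    except Exception as exc:
        raise StageError("synolog_detect", exc) from exc

    try:
        cohort = cohort_summarize([summary], share_decimals=config.share_decimals)
        sio.write_cohort(cohort, paths["cohort"])
    except Exception as exc:
        raise StageError("synolog_stats", exc) from exc

    try:
        calls = call_contexts(
            groups,
            records,
            max_intervening=config.detection.max_intervening,
            window=config.window,
        )
        _write_context(calls, paths["context"])
    except Exception as exc:
        raise StageError("genomic_context", exc) from exc

    return RunResult(
        records=records,
        groups=groups,
        truncated=flagged,
        summary=summary,
        paths=paths,
    )


def _write_context(calls, sink) -> None:
    import json

    import pandas as pd

    pd.DataFrame(
        [
            {
                "group_id": c.group_id,
                "arrangement": c.arrangement,
                "contig_count": c.contig_count,
                "window": c.window,
                "neighbor_profile": json.dumps(c.neighbor_profile, sort_keys=True),
            }
            for c in calls
        ],
        columns=[
            "group_id", "arrangement", "contig_count", "window",
            "neighbor_profile",
        ],
    ).to_csv(sink, sep="\t", index=False)


def cohort_from_summary_files(
    sources: Sequence[Path], share_decimals: int = 1
):
    """Pool per-genome summary TSVs (one or many genomes each) into a cohort."""
    summaries: List[GenomeSynologSummary] = []
    for src in sources:
        summaries.extend(sio.read_summaries(src))
    return cohort_summarize(summaries, share_decimals=share_decimals)
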