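"""End-to-end pipeline driver: files in, result tables out.

`run_pipeline` wires the stages together — parse segments and metadata,
label dissemination, apply strata filters, build the breakpoint-union grid,
scan the requested alteration types, select candidate regions — and writes
everything as tab-separated text plus a run log with a config hash so that
identical inputs provably give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .assoc import (
    candidate_regions,
    fisher_scan,
    records_to_frame,
    write_association_table,
    write_candidate_bed,
)
from .cnatype import (
    AlterationType,
    ClassificationThresholds,
    DEFAULT_THRESHOLDS,
    summarize_cohort,
)
from .cohort import UnionGrid
from .segio import (
    ValidationError,
    default_arms,
    filter_analysable,
    label_dissemination,
    parse_arm_file,
    parse_metadata,
    parse_segment_file,
    write_bedgraph,
)

log = logging.getLogger("cnascan")

DEFAULT_SCAN_TYPES = (
    AlterationType.GAIN,
    AlterationType.LOSS,
    AlterationType.REL_GAIN,
    AlterationType.REL_LOSS,
    AlterationType.LOH,
)


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run depends on."""

    segments: str
    metadata: str
    outdir: str
    arms: str | None = None  # None: bundled hg19 arm table
    stages: tuple[str, ...] | None = None  # e.g. ("II", "III"); None: all
    msi: tuple[str, ...] | None = None  # subset of {"MSI-H", "MSS"}; None: all
    exclude_chemo: bool = False
    alterations: tuple[str, ...] = tuple(t.value for t in DEFAULT_SCAN_TYPES)
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS
    p_max: float = 0.05
    or_min: float = 4.0
    seed: int = 0  # recorded for provenance; the scan itself is deterministic

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "segments": str(self.segments),
                "metadata": str(self.metadata),
                "arms": str(self.arms),
                "stages": self.stages,
                "msi": self.msi,
                "exclude_chemo": self.exclude_chemo,
                "alterations": list(self.alterations),
                "thresholds": vars(self.thresholds),
                "p_max": self.p_max,
                "or_min": self.or_min,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a small summary dict of what was written."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    profiles = parse_segment_file(config.segments)
    metas = parse_metadata(config.metadata)
    arms = parse_arm_file(config.arms) if config.arms else default_arms()

    prof_ids = {p.sample_id for p in profiles}
    meta_ids = {m.sample_id for m in metas}
    orphans = sorted(prof_ids ^ meta_ids)
    if orphans:
        raise ValidationError(
            f"segment/metadata sample mismatch; orphan ids: {orphans}"
        )

    metas = filter_analysable(metas)
    kept = {m.sample_id: m for m in metas}
    if config.stages:
        kept = {k: m for k, m in kept.items() if m.stage in config.stages}
        if not kept:
            raise ValidationError(f"no samples left after stage filter {config.stages}")
    if config.msi:
        kept = {k: m for k, m in kept.items() if m.msi in config.msi}
        if not kept:
            raise ValidationError(f"no samples left after MSI filter {config.msi}")
    if config.exclude_chemo:
        kept = {k: m for k, m in kept.items() if not m.adjuvant_chemo}
        if not kept:
            raise ValidationError("no samples left after excluding adjuvant chemotherapy")
    profiles = [p for p in profiles if p.sample_id in kept]
    log.info("analysing %d samples", len(profiles))

    summary = summarize_cohort(profiles, arms, config.thresholds)
    summary.to_csv(outdir / "sample_summary.tsv", sep="\t", index=False)

    labels = {sid: label_dissemination(m) for sid, m in kept.items()}
    grid = UnionGrid.from_profiles(profiles)
    log.info("union grid: %d segments x %d samples", grid.n_intervals, len(grid.samples))

    n_regions = {}
    for alt in config.alterations:
        records = fisher_scan(grid, labels, alt, config.thresholds)
        write_association_table(records, outdir / f"assoc_{alt}.tsv")
        intervals = [(r.chrom, r.start, r.end) for r in records]
        write_bedgraph(intervals, [r.freq_pos for r in records],
                       outdir / f"freq_pos_{alt}.bedgraph")
        write_bedgraph(intervals, [r.freq_neg for r in records],
                       outdir / f"freq_neg_{alt}.bedgraph")
        write_bedgraph(intervals, [r.freq_diff for r in records],
                       outdir / f"freq_diff_{alt}.bedgraph")
        regions = candidate_regions(records, config.p_max, config.or_min)
        write_candidate_bed(regions, outdir / f"candidates_{alt}.bed")
        n_regions[alt] = len(regions)

    run_log = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_samples": len(profiles),
        "n_disseminated": sum(labels.values()),
        "n_segments": grid.n_intervals,
        "candidate_regions": n_regions,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return run_log
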