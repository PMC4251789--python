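"""Simulation-based validation experiments for the scan pipeline.

Each function runs a replicated synthetic-cohort experiment end to end
through the public pipeline (simulate -> union grid -> Fisher scan ->
candidate regions) and reports operating characteristics: planted-lesion
recovery and confidence-interval coverage, whole-genome-duplication call
accuracy and score bimodality, null calibration of the per-segment test,
and the dissociation between relative and absolute loss in duplicated
genomes.  They double as power/calibration tools for planning scans on
real cohorts.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .assoc import candidate_regions, fisher_scan, top_region
from .cnatype import AlterationType, two_component_separation
from .cohort import UnionGrid
from .segio import default_arms
from .simcohort import PlantedLesion, SimulationConfig, simulate_cohort


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _overlaps(region, lesion: PlantedLesion) -> bool:
    return (
        region is not None
        and region.chrom == lesion.chrom
        and region.start < lesion.end
        and lesion.start < region.end
    )


def _scan_cohort(cohort, alteration):
    grid = UnionGrid.from_profiles(cohort.profiles)
    labels = [g == "disseminated" for g in cohort.truth.group]
    return fisher_scan(grid, labels, alteration)


def lesion_recovery(
    n_replicates: int = 100,
    n_disseminated: int = 57,
    n_control: int = 35,
    lesion: PlantedLesion | None = None,
    seed: int = 0,
    p_max: float = 0.05,
    or_min: float = 0.0,
) -> dict:
    """Planted-lesion recovery and CI coverage over seeded replicates.

    For each replicate a CNA-rich (MSS-like) cohort with a group-differential
    relative-loss lesion is simulated and scanned for REL_LOSS.  Recovery:
    the top-ranked discovery region — the most significant run of segments
    at the initial p < 0.05 cut-off — overlaps the planted interval.  (The
    odds-ratio >= 4 effect-size filter belongs to the reporting stage, not
    to discovery; ``or_min`` can impose it here anyway.)  Coverage: the
    exact CMLE confidence interval at the most significant overlapping
    segment contains the odds ratio implied by the planting frequencies.
    """
    lesion = lesion or PlantedLesion()
    target_or = lesion.sample_odds_ratio
    recovered = covered = 0
    for s in _replicate_seeds(seed, n_replicates):
        cfg = SimulationConfig(
            n_disseminated=n_disseminated,
            n_control=n_control,
            quiet_fraction=0.0,
            lesion=lesion,
            seed=int(s),
        )
        records = _scan_cohort(simulate_cohort(cfg), AlterationType.REL_LOSS)
        top = top_region(candidate_regions(records, p_max, or_min))
        if _overlaps(top, lesion):
            recovered += 1
        in_lesion = [
            r for r in records
            if r.chrom == lesion.chrom and r.start < lesion.end and lesion.start < r.end
        ]
        if in_lesion:
            best = min(in_lesion, key=lambda r: r.p)
            if best.or_defined and best.ci_low <= target_or <= best.ci_high:
                covered += 1
    return {
        "n_replicates": n_replicates,
        "recovery_rate": recovered / n_replicates,
        "ci_coverage": covered / n_replicates,
        "target_odds_ratio": target_or,
    }


def wgd_recovery(n_samples: int = 250, seed: int = 0) -> dict:
    """WGD-call accuracy and score bimodality on one mixed simulated cohort.

    Cohort composition follows the generator defaults (a quiet near-diploid
    fraction; duplication in a minority of the CNA-rich samples).  Accuracy
    is agreement of the score>0 call with the simulator's truth; separation
    is the two-cluster separation index of the pooled score distribution
    (>2 = clearly bimodal).
    """
    from .cnatype import summarize_sample

    cfg = SimulationConfig(
        n_disseminated=n_samples // 2,
        n_control=n_samples - n_samples // 2,
        lesion=None,
        seed=seed,
    )
    cohort = simulate_cohort(cfg)
    arms = cohort.config.arms
    scores = []
    calls = []
    for p in cohort.profiles:
        s = summarize_sample(p, arms)
        scores.append(s.wgd_score)
        calls.append(s.wgd_call)
    truth = cohort.truth.wgd.to_numpy()
    calls = np.array(calls)
    return {
        "n_samples": n_samples,
        "accuracy": float((calls == truth).mean()),
        "separation": float(two_component_separation(scores)),
        "scores": np.array(scores),
        "wgd_fraction": float(truth.mean()),
    }


def null_scan_calibration(
    n_replicates: int = 20,
    n_per_group: int = 25,
    background_event_rate: float = 25.0,
    seed: int = 0,
) -> dict:
    """Type-I error of the per-segment Fisher scan under the null.

    The event rate is raised above the generator default so each replicate
    yields on the order of a thousand scannable segments.

    Cohorts are simulated with no planted lesion and group-independent
    backgrounds, so every segment satisfies the null hypothesis; the pooled
    fraction of segments with p < 0.05 estimates the per-segment type-I
    error (Fisher's exact test is conservative, so this sits below 0.05).
    """
    rejected = total = 0
    for s in _replicate_seeds(seed, n_replicates):
        cfg = SimulationConfig(
            n_disseminated=n_per_group,
            n_control=n_per_group,
            quiet_fraction=0.0,
            background_event_rate=background_event_rate,
            lesion=None,
            seed=int(s),
        )
        records = _scan_cohort(simulate_cohort(cfg), AlterationType.REL_LOSS)
        rejected += sum(1 for r in records if r.p < 0.05)
        total += len(records)
    return {
        "n_replicates": n_replicates,
        "n_segments": total,
        "type_i_error": rejected / total,
    }


def relative_absolute_dissociation(
    n_replicates: int = 20,
    n_per_group: int = 100,
    seed: int = 0,
) -> dict:
    """Relative loss in duplicated genomes is invisible to absolute-loss scans.

    Every sample undergoes a whole-genome duplication, so the planted lesion
    takes 4 copies to 2: below 0.67x the (tetraploid) genome average but not
    below the absolute 2-copy threshold.  Reports the per-replicate rates at
    which a candidate region overlapping the lesion is found by the REL_LOSS
    scan (expected: always) and by the absolute LOSS scan (expected: never).
    """
    lesion = PlantedLesion()
    rel_hits = abs_hits = 0
    for s in _replicate_seeds(seed, n_replicates):
        cfg = SimulationConfig(
            n_disseminated=n_per_group,
            n_control=n_per_group,
            quiet_fraction=0.0,
            wgd_prob=1.0,
            lesion=lesion,
            seed=int(s),
        )
        cohort = simulate_cohort(cfg)
        grid = UnionGrid.from_profiles(cohort.profiles)
        labels = [g == "disseminated" for g in cohort.truth.group]
        rel = fisher_scan(grid, labels, AlterationType.REL_LOSS)
        ab = fisher_scan(grid, labels, AlterationType.LOSS)
        if any(_overlaps(r, lesion) for r in candidate_regions(rel, or_min=0.0)):
            rel_hits += 1
        if any(_overlaps(r, lesion) for r in candidate_regions(ab, or_min=0.0)):
            abs_hits += 1
    return {
        "n_replicates": n_replicates,
        "rel_loss_detection_rate": rel_hits / n_replicates,
        "abs_loss_detection_rate": abs_hits / n_replicates,
    }
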