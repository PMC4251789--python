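"""Synthetic tumour-cohort generator with TAPS-style integer output.

Emulates the two genome classes seen in colorectal tumour cohorts:

* *quiet* (MSI-like) genomes: near diploid, a handful of arm or sub-arm
  events;
* *CIN-like* genomes: many events, a configurable fraction having undergone
  a whole-genome duplication (WGD) that doubles every allele.

Every sample starts from the heterozygous diploid state 2m1 on each autosome
arm.  Events are drawn from a minimal grammar sufficient to generate all the
arm states the WGD score distinguishes: single-copy gain, single-copy loss,
copy-neutral LOH (minor allele replaced by the major one), and at most one
WGD.  A group-differential lesion can be planted on a chosen interval: one
copy lost *relative to the current genome* — one physical copy in a diploid
genome (2m1 -> 1m0, an absolute loss), two in a duplicated genome
(4m2 -> 2m1, a relative loss with two copies retained), mirroring how the
same selective event manifests at different ploidies.

Output is purely integer allele-specific states with full arm coverage:
purity, probe noise and segmentation error belong to the upstream caller,
not to this pipeline's input contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .segio import (
    ArmDefinition,
    GenomeSegment,
    SampleMetadata,
    SampleProfile,
    ValidationError,
    canonical_state,
    default_arms,
)


@dataclass(frozen=True)
class PlantedLesion:
    """A group-differential loss lesion on a fixed interval.

    Planted as a spike-in: background events are kept off the interval, so
    the configured frequencies are the observed per-group alteration
    frequencies at the locus and the implied odds ratio is exact.
    """

    chrom: int = 1
    start: int = 0
    end: int = 27_000_000  # 1p36-like region
    freq_disseminated: float = 0.5
    freq_control: float = 0.15

    def __post_init__(self):
        for f in (self.freq_disseminated, self.freq_control):
            if not 0.0 <= f <= 1.0:
                raise ValidationError("lesion frequencies must be in [0, 1]")

    @property
    def sample_odds_ratio(self) -> float:
        """Odds ratio implied by the two planting frequencies."""
        p1, p0 = self.freq_disseminated, self.freq_control
        return (p1 / (1 - p1)) / (p0 / (1 - p0))


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Group sizes default to a disseminated/control split like the cohorts
    such scans are run on; ``quiet_fraction`` of each group is MSI-like.
    ``wgd_prob`` applies to CIN-like samples only.  Event counts are Poisson
    with the given means; each event is whole-arm with probability
    ``whole_arm_prob``, otherwise sub-arm with exponential length
    ``subarm_mean_length``.  A fixed ``seed`` makes the cohort bit-identical
    across runs.
    """

    arms: tuple[ArmDefinition, ...] = None  # default: bundled hg19 arms
    n_disseminated: int = 63
    n_control: int = 53
    quiet_fraction: float = 0.2
    wgd_prob: float = 0.4
    pre_wgd_events: int = 0
    background_event_rate: float = 8.0
    quiet_event_rate: float = 3.0
    whole_arm_prob: float = 0.45
    subarm_mean_length: float = 20e6
    min_event_length: int = 500_000
    lesion: PlantedLesion | None = field(default_factory=PlantedLesion)
    seed: int = 0

    def __post_init__(self):
        if self.arms is None:
            object.__setattr__(self, "arms", tuple(default_arms()))
        else:
            object.__setattr__(self, "arms", tuple(self.arms))
        for name in ("quiet_fraction", "wgd_prob", "whole_arm_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.lesion is not None:
            ok = any(
                a.chrom == self.lesion.chrom
                and a.start < self.lesion.end
                and self.lesion.start < a.end
                for a in self.arms
            )
            if not ok:
                raise ValidationError("planted lesion interval is outside the genome")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        lesion = raw.pop("lesion", "default")
        kwargs = dict(raw)
        if lesion is None:
            kwargs["lesion"] = None
        elif lesion != "default":
            kwargs["lesion"] = PlantedLesion(**lesion)
        return cls(**kwargs)


# -- in-progress genome representation: per-arm list of [start, end, t, m] --


def _blank_genome(arms: Sequence[ArmDefinition]) -> dict[int, list[list[int]]]:
    genome: dict[int, list[list[int]]] = {}
    for a in arms:
        genome.setdefault(a.chrom, []).append([a.start, a.end, 2, 1])
    for segs in genome.values():
        segs.sort()
    return genome


def _overlay(genome, chrom: int, lo: int, hi: int, fn) -> None:
    """Apply state transform fn(t, m) -> (t, m) to [lo, hi) on one chromosome,
    splitting segments at the event boundaries."""
    segs = genome[chrom]
    out = []
    for start, end, t, m in segs:
        a, b = max(start, lo), min(end, hi)
        if a >= b:
            out.append([start, end, t, m])
            continue
        if start < a:
            out.append([start, a, t, m])
        nt, nm = fn(t, m)
        nt, nm = canonical_state(int(nt), int(nm))
        out.append([a, b, nt, nm])
        if b < end:
            out.append([b, end, t, m])
    genome[chrom] = out


def _apply_wgd(genome) -> None:
    for segs in genome.values():
        for s in segs:
            s[2] *= 2
            s[3] *= 2


def _loss(t, m):
    if t == 0:
        return 0, 0
    # one copy of a random-free choice: take it from the major allele, the
    # more abundant homolog (losses of the last minor copy are the m -> m-1
    # path below when major == minor)
    return t - 1, min(m, (t - 1) - m if (t - 1) - m >= 0 else 0)


def _gain(t, m):
    return t + 1, m


def _cnloh(t, m):
    return t, 0


def _draw_event_interval(cfg: SimulationConfig, rng: np.random.Generator):
    arm = cfg.arms[rng.integers(len(cfg.arms))]
    if rng.random() < cfg.whole_arm_prob:
        return arm.chrom, arm.start, arm.end
    length = max(cfg.min_event_length, int(rng.exponential(cfg.subarm_mean_length)))
    length = min(length, arm.length)
    start = int(arm.start + rng.integers(0, arm.length - length + 1))
    return arm.chrom, start, start + length


_EVENT_FNS = (_gain, _loss, _cnloh)


def _apply_background(genome, cfg, rng, n_events: int) -> None:
    # Spike-in purity: background events are redrawn if they touch the
    # planted interval, so the lesion's observed group frequencies are
    # exactly the configured planting frequencies.
    les = cfg.lesion
    for _ in range(n_events):
        for _attempt in range(100):
            chrom, lo, hi = _draw_event_interval(cfg, rng)
            if les is None or chrom != les.chrom or hi <= les.start or les.end <= lo:
                break
        else:  # pragma: no cover - genome nearly all lesion
            continue
        fn = _EVENT_FNS[rng.integers(3)]
        _overlay(genome, chrom, lo, hi, fn)


def _genome_to_profile(sample_id: str, genome) -> SampleProfile:
    segs = []
    for chrom in sorted(genome):
        # merge touching equal-state pieces for a tidy profile
        for start, end, t, m in genome[chrom]:
            if (
                segs
                and segs[-1].chrom == chrom
                and segs[-1].end == start
                and segs[-1].state == (t, m)
            ):
                last = segs.pop()
                segs.append(GenomeSegment(chrom, last.start, end, t, m))
            else:
                segs.append(GenomeSegment(chrom, start, end, t, m))
    return SampleProfile(sample_id, segs)


def simulate_profile(
    config: SimulationConfig,
    group: Literal["disseminated", "control"],
    rng: np.random.Generator,
    sample_id: str = "S1",
) -> tuple[SampleProfile, SampleMetadata, dict]:
    """Draw one sample: profile, clinical metadata and ground-truth record.

    Order of events: (quiet?) -> optional pre-WGD events -> WGD (CIN class,
    probability ``wgd_prob``) -> Poisson background events -> planted lesion
    (Bernoulli with the group's frequency).
    """
    genome = _blank_genome(config.arms)
    quiet = rng.random() < config.quiet_fraction
    wgd = False
    if quiet:
        n_events = rng.poisson(config.quiet_event_rate)
        _apply_background(genome, config, rng, n_events)
    else:
        _apply_background(genome, config, rng, config.pre_wgd_events)
        wgd = rng.random() < config.wgd_prob
        if wgd:
            _apply_wgd(genome)
        n_events = rng.poisson(config.background_event_rate)
        _apply_background(genome, config, rng, n_events)

    lesion = False
    if config.lesion is not None:
        freq = (
            config.lesion.freq_disseminated
            if group == "disseminated"
            else config.lesion.freq_control
        )
        lesion = rng.random() < freq
        if lesion:
            copies = 2 if wgd else 1
            _overlay(
                genome,
                config.lesion.chrom,
                config.lesion.start,
                config.lesion.end,
                lambda t, m: (max(t - copies, 0), max(m - copies // 2, 0)),
            )

    if group == "disseminated":
        stage_iv = rng.random() < 0.35
        meta = SampleMetadata(
            sample_id=sample_id,
            stage="IV" if stage_iv else ("II" if rng.random() < 0.4 else "III"),
            msi="MSI-H" if quiet else "MSS",
            distant_recurrence=not stage_iv,
            followup_years=None if stage_iv else float(rng.uniform(0.5, 4.5)),
            adjuvant_chemo=bool(rng.random() < 0.5),
        )
    else:
        meta = SampleMetadata(
            sample_id=sample_id,
            stage="II" if rng.random() < 0.5 else "III",
            msi="MSI-H" if quiet else "MSS",
            distant_recurrence=False,
            followup_years=float(rng.uniform(5.5, 10.0)),
            adjuvant_chemo=bool(rng.random() < 0.4),
        )
    truth = dict(
        sample=sample_id,
        group=group,
        genome_class="quiet" if quiet else "cin",
        wgd=wgd,
        lesion=lesion,
    )
    return _genome_to_profile(sample_id, genome), meta, truth


@dataclass(frozen=True)
class SimulatedCohort:
    profiles: tuple[SampleProfile, ...]
    metadata: tuple[SampleMetadata, ...]
    truth: pd.DataFrame
    config: SimulationConfig


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw the full cohort with per-sample deterministic substreams.

    Each sample has its own generator spawned from (seed, sample index), so
    cohorts are reproducible independent of iteration order.
    """
    root = np.random.SeedSequence(config.seed)
    n = config.n_disseminated + config.n_control
    streams = root.spawn(n)
    profiles, metas, truths = [], [], []
    for i in range(n):
        group = "disseminated" if i < config.n_disseminated else "control"
        k = i if group == "disseminated" else i - config.n_disseminated
        sid = f"{'D' if group == 'disseminated' else 'C'}{k + 1:03d}"
        rng = np.random.default_rng(streams[i])
        prof, meta, truth = simulate_profile(config, group, rng, sample_id=sid)
        profiles.append(prof)
        metas.append(meta)
        truths.append(truth)
    return SimulatedCohort(
        profiles=tuple(profiles),
        metadata=tuple(metas),
        truth=pd.DataFrame(truths),
        config=config,
    )
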