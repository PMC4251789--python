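import numpy as np
import pytest

from cnascan import ArmDefinition, GenomeSegment, SampleProfile, canonical_state


@pytest.fixture
def toy_arms():
    """A two-chromosome toy genome: each chromosome 10 kb with a 1 kb
    centromere gap between 4.5 and 5.5 kb."""
    return (
        ArmDefinition(1, "p", 0, 4500),
        ArmDefinition(1, "q", 5500, 10_000),
        ArmDefinition(2, "p", 0, 4500),
        ArmDefinition(2, "q", 5500, 10_000),
    )


def make_profile(sample_id, segs):
    """segs: iterable of (chrom, start, end, total, minor) with raw minor."""
    return SampleProfile(
        sample_id,
        [GenomeSegment(c, s, e, *canonical_state(t, m)) for c, s, e, t, m in segs],
    )


@pytest.fixture
def flat_diploid():
    """One sample, uniformly 2m1 on chr1 [0, 10000)."""
    return make_profile("flat", [(1, 0, 10_000, 2, 1)])


def random_toy_cohort(rng, n_samples=5, genome_len=10_000, max_segs=8,
                      gap_prob=0.2):
    """Random single-chromosome cohort for grid oracle tests.

    Each sample: sorted random breakpoints partition [0, genome_len); each
    piece is either a gap (missing) or a random allele-specific state.
    """
    profiles = []
    for i in range(n_samples):
        k = rng.integers(1, max_segs + 1)
        cuts = np.sort(rng.choice(np.arange(1, genome_len), size=k, replace=False))
        bounds = [0, *cuts.tolist(), genome_len]
        segs = []
        for lo, hi in zip(bounds, bounds[1:]):
            if rng.random() < gap_prob:
                continue
            t = int(rng.integers(0, 6))
            m = int(rng.integers(0, t + 1)) if t else 0
            t, m = canonical_state(t, m)
            segs.append(GenomeSegment(1, int(lo), int(hi), t, m))
        if not segs:  # keep every sample non-empty
            segs.append(GenomeSegment(1, 0, genome_len, 2, 1))
        profiles.append(SampleProfile(f"S{i}", segs))
    return profiles


def per_base_states(profile, genome_len):
    """Brute-force oracle: (total, minor) arrays over every base, -1 = gap."""
    total = np.full(genome_len, -1, dtype=int)
    minor = np.full(genome_len, -1, dtype=int)
    for s in profile.segments:
        total[s.start:s.end] = s.total_cn
        minor[s.start:s.end] = s.minor_cn
    return total, minor
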