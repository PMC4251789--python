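import numpy as np
import pytest

from cnascan import (
    AlterationType as AT,
    ArmDefinition,
    ClassificationThresholds,
    GenomeSegment,
    ValidationError,
    arm_median_state,
    average_ploidy,
    classify_cin,
    classify_segment,
    cna_burden,
    summarize_sample,
    two_component_separation,
    wgd_score,
)
from cnascan.cnatype import _weighted_median_int

from conftest import make_profile

MB = 1_000_000


class TestAveragePloidy:
    def test_uniform_diploid(self):
        p = make_profile("A", [(1, 0, 3000 * MB, 2, 1)])
        assert average_ploidy(p) == 2.0

    def test_length_weighted_mean(self):
        p = make_profile("A", [(1, 0, 3000 * MB, 2, 1), (2, 0, 200 * MB, 4, 2)])
        assert average_ploidy(p) == pytest.approx((3000 * 2 + 200 * 4) / 3200)

    def test_tetraploid_is_hyperploid(self, toy_arms):
        p = make_profile("A", [(a.chrom, a.start, a.end, 4, 2) for a in toy_arms])
        s = summarize_sample(p, toy_arms)
        assert s.avg_ploidy == 4.0 and s.hyperploid  # 4.0 > 2.5

    def test_invariant_under_segment_splitting(self):
        whole = make_profile("A", [(1, 0, 100, 3, 1)])
        split = make_profile("A", [(1, 0, 37, 3, 1), (1, 37, 61, 3, 1), (1, 61, 100, 3, 1)])
        assert average_ploidy(whole) == average_ploidy(split)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValidationError):
            average_ploidy(make_profile("A", []))


def seg(total, minor, length=5 * MB):
    return GenomeSegment(1, 0, length, total, minor)


class TestClassifySegment:
    @pytest.mark.parametrize(
        "total,minor,ploidy,length,expected",
        [
            # deep diploid loss: absolute + relative + LOH
            (1, 0, 2.0, 5 * MB, {AT.LOSS, AT.REL_LOSS, AT.LOH}),
            # three copies in a near-tetraploid genome: absolute gain only;
            # 3 >= 0.67*3.8 so no relative loss despite being below ploidy
            (3, 1, 3.8, 5 * MB, {AT.GAIN}),
            # copy-neutral LOH, the 2m0 state
            (2, 0, 2.0, 5 * MB, {AT.LOH}),
            # homozygous deletion implies absolute loss and LOH
            (0, 0, 2.0, 5 * MB, {AT.HOMDEL, AT.LOSS, AT.REL_LOSS, AT.LOH}),
            # focal calls need < 1 Mb
            (1, 0, 2.0, 500_000, {AT.LOSS, AT.REL_LOSS, AT.LOH, AT.FOCAL_LOSS}),
            (5, 1, 2.0, 500_000, {AT.GAIN, AT.REL_GAIN, AT.FOCAL_GAIN}),
            # high gain: more than 3 copies above average ploidy
            (6, 2, 2.5, 5 * MB, {AT.GAIN, AT.REL_GAIN, AT.HIGH_GAIN}),
            # normal state: nothing
            (2, 1, 2.0, 5 * MB, set()),
        ],
    )
    def test_examples(self, total, minor, ploidy, length, expected):
        assert classify_segment(seg(total, minor, length), ploidy) == expected

    def test_consistency_at_diploid_ploidy(self):
        # at ploidy 2.0 every absolute loss is a relative loss (1 < 1.34)
        # and every total >= 3 is a relative gain (3 > 2.5)
        for total in range(0, 8):
            calls = classify_segment(seg(total, 0), 2.0)
            if AT.LOSS in calls:
                assert AT.REL_LOSS in calls
            if total >= 3:
                assert AT.REL_GAIN in calls

    def test_homdel_implies_loss_and_loh(self):
        for ploidy in (1.5, 2.0, 3.7):
            calls = classify_segment(seg(0, 0), ploidy)
            assert {AT.HOMDEL, AT.LOSS, AT.LOH} <= calls

    def test_strict_inequalities_at_relative_thresholds(self):
        # exactly 1.25x ploidy is not a relative gain; exactly 0.67x not a loss
        assert AT.REL_GAIN not in classify_segment(seg(5, 2), 4.0)
        thr = ClassificationThresholds(rel_loss_factor=0.5)
        assert AT.REL_LOSS not in classify_segment(seg(2, 1), 4.0, thr)


ARM = ArmDefinition(1, "p", 0, 100)


class TestArmMedianState:
    def test_uniform_arm(self):
        p = make_profile("A", [(1, 0, 100, 2, 1)])
        assert arm_median_state(p, ARM) == (2, 1)

    def test_majority_by_length(self):
        p = make_profile("A", [(1, 0, 60, 4, 2), (1, 60, 100, 2, 1)])
        assert arm_median_state(p, ARM) == (4, 2)

    def test_even_tie_takes_lower_median(self):
        p = make_profile("A", [(1, 0, 50, 4, 2), (1, 50, 100, 2, 1)])
        assert arm_median_state(p, ARM) == (2, 1)

    def test_no_coverage_gives_none(self):
        p = make_profile("A", [(2, 0, 100, 2, 1)])
        assert arm_median_state(p, ARM) is None

    def test_medians_computed_independently(self):
        # total median and minor median can come from different segments
        p = make_profile("A", [(1, 0, 60, 4, 0), (1, 60, 100, 2, 1)])
        assert arm_median_state(p, ARM) == (4, 0)

    @pytest.mark.parametrize("seed", range(25))
    def test_against_expanded_base_vector_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(1, 6)
        bounds = np.sort(rng.choice(np.arange(1, 100), size=k, replace=False))
        bounds = [0, *bounds.tolist(), 100]
        segs, tot_bases, mnr_bases = [], [], []
        for lo, hi in zip(bounds, bounds[1:]):
            t = int(rng.integers(0, 6))
            m = int(rng.integers(0, t + 1)) if t else 0
            m = min(m, t - m)
            segs.append((1, lo, hi, t, m))
            tot_bases += [t] * (hi - lo)
            mnr_bases += [m] * (hi - lo)
        p = make_profile("A", segs)
        got = arm_median_state(p, ARM)
        # lower median of the fully expanded per-base vectors
        def lower_median(v):
            v = sorted(v)
            n = len(v)
            return v[(n - 1) // 2] if n % 2 else v[n // 2 - 1]
        assert got == (lower_median(tot_bases), lower_median(mnr_bases))


class TestWgdScore:
    def test_pure_diploid(self):
        assert wgd_score([(2, 1)] * 44) == -44

    def test_pure_post_wgd_tetraploid(self):
        assert wgd_score([(4, 2)] * 44) == 44

    def test_other_states_contribute_zero(self):
        states = [(2, 0)] * 10 + [(2, 1)] * 30 + [(3, 1)] * 4
        assert wgd_score(states) == 10 - 30

    def test_missing_arms_skipped(self):
        assert wgd_score([(2, 1), None, (4, 2), None]) == 0

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            wgd_score([None, None])

    def test_doubling_flips_pure_diploid_score(self, toy_arms):
        base = make_profile("A", [(a.chrom, a.start, a.end, 2, 1) for a in toy_arms])
        doubled = make_profile("A", [(a.chrom, a.start, a.end, 4, 2) for a in toy_arms])
        n = len(toy_arms)
        assert summarize_sample(base, toy_arms).wgd_score == -n
        assert summarize_sample(doubled, toy_arms).wgd_score == +n

    def test_weighted_median_lower_tie(self):
        assert _weighted_median_int(np.array([2, 4]), np.array([5, 5])) == 2
        assert _weighted_median_int(np.array([4, 2]), np.array([6, 4])) == 4


class TestCin:
    def test_flat_genome_not_cin(self):
        p = make_profile("A", [(c, 0, 50 * MB, 2, 1) for c in range(1, 23)])
        assert not classify_cin(p)

    def test_five_chromosomes_with_large_losses(self):
        segs = []
        for c in range(1, 23):
            if c <= 5:
                segs += [(c, 0, 12 * MB, 1, 0), (c, 12 * MB, 50 * MB, 2, 1)]
            else:
                segs.append((c, 0, 50 * MB, 2, 1))
        assert classify_cin(make_profile("A", segs))

    def test_four_large_plus_one_small_is_not_cin(self):
        segs = []
        for c in range(1, 23):
            if c <= 4:
                segs += [(c, 0, 12 * MB, 1, 0), (c, 12 * MB, 50 * MB, 2, 1)]
            elif c == 5:
                segs += [(c, 0, 8 * MB, 1, 0), (c, 8 * MB, 50 * MB, 2, 1)]
            else:
                segs.append((c, 0, 50 * MB, 2, 1))
        assert not classify_cin(make_profile("A", segs))

    def test_adjacent_equal_state_runs_merged_before_length_test(self):
        # two contiguous 6 Mb pieces of the same altered state pass the
        # 10 Mb rule only because they merge
        segs = []
        for c in range(1, 23):
            if c <= 5:
                segs += [
                    (c, 0, 6 * MB, 1, 0),
                    (c, 6 * MB, 12 * MB, 1, 0),
                    (c, 12 * MB, 50 * MB, 2, 1),
                ]
            else:
                segs.append((c, 0, 50 * MB, 2, 1))
        assert classify_cin(make_profile("A", segs))


class TestBurden:
    def test_flat_genome(self):
        p = make_profile("A", [(c, 0, 50 * MB, 2, 1) for c in range(1, 23)])
        assert cna_burden(p) == (0, 0.0)

    def test_single_loh_region(self):
        segs = [(1, 0, 87 * MB, 2, 0), (1, 87 * MB, 140 * MB, 2, 1)]
        segs += [(c, 0, 50 * MB, 2, 1) for c in range(2, 23)]
        assert cna_burden(make_profile("A", segs)) == (1, 87.0)

    def test_whole_genome_tetraploid(self):
        # 22 chromosomes, ~3100 Mb total, all altered
        per = 3100 * MB // 22
        p = make_profile("A", [(c, 0, per, 4, 2) for c in range(1, 23)])
        n, mb = cna_burden(p)
        assert n == 22 and mb == pytest.approx(22 * per / 1e6)

    def test_cnloh_switch(self):
        segs = [(1, 0, 87 * MB, 2, 0), (1, 87 * MB, 140 * MB, 2, 1)]
        p = make_profile("A", segs)
        assert cna_burden(p, include_cnloh=False) == (0, 0.0)


class TestTwoComponentSeparation:
    def test_well_separated_modes(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-40, 3, 100), rng.normal(20, 3, 60)])
        assert two_component_separation(x) > 2

    def test_single_mode_scores_low(self):
        rng = np.random.default_rng(1)
        assert two_component_separation(rng.normal(0, 5, 200)) < 2
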