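import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnascan import (
    AssociationRecord,
    UnionGrid,
    ValidationError,
    bh_adjust,
    candidate_regions,
    contingency_test,
    fisher_scan,
    odds_ratio_ci,
    top_region,
)
from cnascan.assoc import (
    fisher_p,
    read_association_table,
    write_association_table,
)

from conftest import make_profile


def fisher_two_sided_oracle(a, b, c, d):
    """Independent enumeration of the two-sided Fisher exact p-value.

    Sums point probabilities of every table with the observed margins whose
    noncentral-free hypergeometric probability does not exceed that of the
    observed table (with a tiny relative slack for float ties).
    """
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    denom = math.comb(n, r1)

    def point(x):
        return math.comb(c1, x) * math.comb(n - c1, r1 - x) / denom

    p_obs = point(a)
    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    return sum(point(x) for x in range(lo, hi + 1) if point(x) <= p_obs * (1 + 1e-7))


class TestFisherP:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            assert fisher_p(int(a), int(b), int(c), int(d)) == pytest.approx(
                fisher_two_sided_oracle(int(a), int(b), int(c), int(d)), rel=1e-9
            )

    def test_one_sided_tail_example(self):
        # (0,3;53,60): lower tail = hypergeometric P(0) = C(63,3)/C(116,3)
        expect = math.comb(63, 3) / math.comb(116, 3)
        _, p = contingency_test([[0, 3], [53, 60]], "fisher_one_sided")
        assert p == pytest.approx(expect, rel=1e-9)
        assert p == pytest.approx(0.157, abs=5e-4)


class TestOddsRatio:
    def test_sample_or_arithmetic(self):
        est, lo, hi = odds_ratio_ci(17, 7, 35, 57, method="sample")
        assert est == pytest.approx(17 * 57 / (7 * 35))
        assert lo < est < hi

    def test_symmetric_table(self):
        est, lo, hi = odds_ratio_ci(1, 1, 1, 1, method="cmle")
        assert est == pytest.approx(1.0, abs=1e-6)
        assert lo < 1 < hi

    def test_haldane_correction_on_zero_cell(self):
        est, _, _ = odds_ratio_ci(5, 0, 5, 10, method="sample")
        assert est == pytest.approx((5.5 * 10.5) / (0.5 * 5.5))  # 21.0

    def test_cmle_zero_cell_gives_infinite_upper_bound(self):
        est, lo, hi = odds_ratio_ci(5, 0, 5, 10, method="cmle")
        assert est == math.inf and math.isfinite(lo) and hi == math.inf

    def test_zero_margin_is_undefined(self):
        est, lo, hi = odds_ratio_ci(0, 0, 5, 10)
        assert math.isnan(est) and math.isnan(lo) and math.isnan(hi)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            odds_ratio_ci(-1, 1, 1, 1)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(1, 20), st.integers(1, 20), st.integers(1, 20), st.integers(1, 20))
    def test_sample_or_monotone_in_a(self, a, b, c, d):
        lo, _, _ = odds_ratio_ci(a, b, c, d, method="sample")
        hi, _, _ = odds_ratio_ci(a + 1, b, c, d, method="sample")
        assert hi >= lo


TABLE1 = [
    # (label, table, method, printed p)
    ("gender", [[24, 24], [29, 39]], "chi2", 0.434),
    ("location", [[33, 37], [20, 26]], "chi2", 0.698),
    ("differentiation", [[41, 48], [12, 15]], "chi2", 0.882),
    ("tumour_size", [[12, 25], [40, 38]], "chi2", 0.058),
    ("mucinous", [[11, 8], [42, 55]], "chi2", 0.243),
    ("vascular_invasion", [[6, 10], [47, 53]], "chi2", 0.479),
    ("perineural_invasion", [[0, 3], [53, 60]], "fisher_one_sided", 0.157),
    ("msi", [[17, 7], [35, 57]], "chi2_yates", 0.008),
]


class TestContingency:
    @pytest.mark.parametrize("label,table,method,expected",
                             TABLE1, ids=[t[0] for t in TABLE1])
    def test_clinical_cross_tables(self, label, table, method, expected):
        _, p = contingency_test(table, method)
        assert round(p, 3) == expected

    def test_identical_rows_give_chi2_zero(self):
        stat, p = contingency_test([[10, 20], [10, 20]], "chi2")
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_zero_margin_rejected_for_chi2(self):
        with pytest.raises(ValidationError):
            contingency_test([[0, 0], [5, 10]], "chi2")


def rec(chrom, start, end, p=0.5, orr=1.0, alteration="REL_LOSS"):
    return AssociationRecord(
        chrom=chrom, start=start, end=end, alteration=alteration,
        a=1, b=1, c=1, d=1, freq_pos=0.5, freq_neg=0.5, freq_diff=0.0,
        p=p, or_estimate=orr, ci_low=orr / 2, ci_high=orr * 2,
        or_defined=not math.isnan(orr),
    )


class TestCandidateRegions:
    def test_no_significant_segment_gives_empty_set(self):
        assert candidate_regions([rec(1, 0, 10), rec(1, 10, 20)]) == []

    def test_adjacent_qualifying_segments_merge(self):
        recs = [rec(1, i * 10, (i + 1) * 10, p=0.01, orr=5 + i) for i in range(3)]
        (region,) = candidate_regions(recs)
        assert (region.start, region.end, region.n_segments) == (0, 30, 3)
        assert region.peak_or == 7 and region.min_p == 0.01

    def test_non_qualifying_gap_splits_regions(self):
        recs = [
            rec(1, 0, 10, p=0.01, orr=5),
            rec(1, 10, 20, p=0.5, orr=5),
            rec(1, 20, 30, p=0.01, orr=5),
        ]
        assert len(candidate_regions(recs)) == 2

    def test_chromosome_boundary_splits_regions(self):
        recs = [rec(1, 0, 10, p=0.01, orr=5), rec(2, 0, 10, p=0.001, orr=6)]
        regions = candidate_regions(recs)
        assert len(regions) == 2
        assert top_region(regions).chrom == 2

    def test_or_threshold_enforced(self):
        assert candidate_regions([rec(1, 0, 10, p=0.001, orr=3.9)]) == []
        assert len(candidate_regions([rec(1, 0, 10, p=0.001, orr=4.0)])) == 1

    def test_undefined_or_never_qualifies(self):
        assert candidate_regions([rec(1, 0, 10, p=0.001, orr=math.nan)]) == []

    def test_mixed_alteration_types_rejected(self):
        with pytest.raises(ValidationError):
            candidate_regions([rec(1, 0, 10), rec(1, 10, 20, alteration="LOSS")])


class TestFisherScan:
    def make_grid(self):
        # 4 samples; B and D carry a loss on [0, 10)
        profiles = [
            make_profile("A", [(1, 0, 20, 2, 1)]),
            make_profile("B", [(1, 0, 10, 1, 0), (1, 10, 20, 2, 1)]),
            make_profile("C", [(1, 0, 20, 2, 1)]),
            make_profile("D", [(1, 0, 10, 1, 0), (1, 10, 20, 2, 1)]),
        ]
        return UnionGrid.from_profiles(profiles)

    def test_counts_and_frequencies(self):
        grid = self.make_grid()
        labels = {"A": True, "B": True, "C": False, "D": False}
        first, second = fisher_scan(grid, labels, "LOSS")
        assert (first.a, first.b, first.c, first.d) == (1, 1, 1, 1)
        assert first.freq_pos == 0.5 and first.freq_neg == 0.5
        assert first.p == 1.0
        assert (second.a, second.b) == (0, 0) and second.p == 1.0

    def test_all_unaltered_segment_has_p_one_and_zero_diff(self):
        grid = self.make_grid()
        labels = {"A": True, "B": True, "C": False, "D": False}
        _, second = fisher_scan(grid, labels, "LOSS")
        assert second.freq_diff == 0.0 and second.p == 1.0

    def test_missing_states_shrink_denominators(self):
        profiles = [
            make_profile("A", [(1, 0, 20, 1, 0)]),
            make_profile("B", [(1, 10, 20, 2, 1)]),  # gap on [0, 10)
            make_profile("C", [(1, 0, 20, 2, 1)]),
        ]
        grid = UnionGrid.from_profiles(profiles)
        labels = {"A": True, "B": True, "C": False}
        first = fisher_scan(grid, labels, "LOSS")[0]
        # B is missing on [0,10): disseminated denominator is 1, not 2
        assert (first.a + first.c, first.b + first.d) == (1, 1)

    def test_group_empty_at_segment_flagged(self):
        profiles = [
            make_profile("A", [(1, 0, 10, 1, 0)]),
            make_profile("B", [(1, 5, 10, 2, 1)]),
        ]
        grid = UnionGrid.from_profiles(profiles)
        labels = {"A": True, "B": False}
        first = fisher_scan(grid, labels, "LOSS")[0]  # [0,5): only A covered
        assert first.p == 1.0 and not first.or_defined

    def test_labels_must_cover_grid(self):
        grid = self.make_grid()
        with pytest.raises(ValidationError, match="missing"):
            fisher_scan(grid, {"A": True}, "LOSS")

    def test_association_table_roundtrip(self, tmp_path):
        grid = self.make_grid()
        labels = {"A": True, "B": True, "C": False, "D": False}
        records = fisher_scan(grid, labels, "LOSS")
        path = tmp_path / "assoc.tsv"
        write_association_table(records, path)
        back = read_association_table(path)
        assert len(back) == len(records)
        for r1, r2 in zip(records, back):
            for f in ("chrom", "start", "end", "a", "b", "c", "d", "alteration"):
                assert getattr(r1, f) == getattr(r2, f)
            assert r2.p == pytest.approx(r1.p)


class TestBH:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        ours = bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, ref)
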