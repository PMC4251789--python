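"""Segment-level association of copy-number alterations with an outcome.

For each breakpoint-union segment, samples are cross-classified as
altered/unaltered x disseminated/non-disseminated and tested with Fisher's
exact test (two-sided by point-probability summation, the convention of
scipy and R's ``fisher.test``).  Effect sizes are odds ratios — by default
the conditional maximum-likelihood estimate (CMLE) under the noncentral
hypergeometric model with its exact 95% confidence interval, which remains
defined (possibly 0 or infinite) when cells are empty.  P-values are
reported unadjusted; a Benjamini-Hochberg column is available as optional
plumbing.

Candidate regions are maximal runs of adjacent segments that pass both a
significance cut-off (p < 0.05) and an effect-size cut-off (OR >= 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .cnatype import (
    AlterationType,
    ClassificationThresholds,
    DEFAULT_THRESHOLDS,
    call_matrix,
    grid_ploidies,
)
from .cohort import UnionGrid
from .segio import ValidationError


@lru_cache(maxsize=200_000)
def fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]]).pvalue)


@lru_cache(maxsize=100_000)
def _cmle_or_ci(a: int, b: int, c: int, d: int, level: float) -> tuple[float, float, float]:
    res = _scipy_odds_ratio([[a, b], [c, d]], kind="conditional")
    ci = res.confidence_interval(level)
    return float(res.statistic), float(ci.low), float(ci.high)


def odds_ratio_ci(
    a: int,
    b: int,
    c: int,
    d: int,
    method: Literal["cmle", "sample"] = "cmle",
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Odds ratio and confidence interval for a 2x2 table [[a, b], [c, d]].

    ``cmle``: conditional maximum-likelihood estimate under the noncentral
    hypergeometric model with exact CI (zero cells give 0/inf bounds).
    ``sample``: the cross-product ratio a*d / (b*c), with the
    Haldane-Anscombe +0.5 correction when any cell is zero, and a Woolf
    (logit) interval.

    A zero row or column margin leaves the odds ratio undefined: returns
    (nan, nan, nan).
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("negative cell count")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return (math.nan, math.nan, math.nan)
    if method == "cmle":
        return _cmle_or_ci(a, b, c, d, level)
    if method != "sample":
        raise ValueError(f"unknown odds-ratio method {method!r}")
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    est = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = stats.norm.ppf(0.5 + level / 2)
    return (est, est * math.exp(-z * se), est * math.exp(z * se))


def contingency_test(
    table: Sequence[Sequence[float]],
    method: Literal["chi2", "chi2_yates", "fisher_two_sided", "fisher_one_sided"],
) -> tuple[float, float]:
    """(statistic, p) for a 2x2 clinical contingency table.

    ``chi2`` is the Pearson chi-square without continuity correction (df=1);
    ``chi2_yates`` applies the Yates correction.  The one-sided Fisher test
    uses the lower tail (P of a table at most as extreme in the [0][0] cell).
    Fisher variants report the odds-ratio-free statistic as nan.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("need a non-negative 2x2 table")
    if method in ("chi2", "chi2_yates"):
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            raise ValidationError("chi-square undefined with a zero margin")
        res = stats.chi2_contingency(t, correction=(method == "chi2_yates"))
        return float(res.statistic), float(res.pvalue)
    if method == "fisher_two_sided":
        res = stats.fisher_exact(t.astype(int))
        return (math.nan, float(res.pvalue))
    if method == "fisher_one_sided":
        res = stats.fisher_exact(t.astype(int), alternative="less")
        return (math.nan, float(res.pvalue))
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class AssociationRecord:
    """Per-segment 2x2 association of one alteration type with dissemination.

    a = altered & disseminated, b = altered & non-disseminated,
    c = unaltered & disseminated, d = unaltered & non-disseminated;
    samples with missing state at the segment are excluded from all four
    cells, so a+c and b+d vary by segment.  ``or_defined`` is False when a
    zero margin leaves the odds ratio meaningless.
    """

    chrom: int
    start: int
    end: int
    alteration: str
    a: int
    b: int
    c: int
    d: int
    freq_pos: float
    freq_neg: float
    freq_diff: float
    p: float
    or_estimate: float
    ci_low: float
    ci_high: float
    or_defined: bool


def fisher_scan(
    grid: UnionGrid,
    labels: dict[str, bool] | Sequence[bool],
    alteration: AlterationType | str,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    ploidies: np.ndarray | None = None,
    or_method: Literal["cmle", "sample"] = "cmle",
) -> list[AssociationRecord]:
    """Scan every union segment for association with the outcome labels.

    ``labels`` maps sample id -> disseminated flag (or is a boolean sequence
    aligned with ``grid.samples``).  Relative alteration types need per-
    sample average ploidies; these default to length-weighted means over the
    grid, which equal profile ploidies when coverage is complete.
    """
    if isinstance(labels, dict):
        missing = [s for s in grid.samples if s not in labels]
        if missing:
            raise ValidationError(f"labels missing for samples: {missing}")
        lab = np.array([bool(labels[s]) for s in grid.samples])
    else:
        lab = np.asarray(labels, dtype=bool)
        if lab.shape != (len(grid.samples),):
            raise ValidationError("labels length does not match grid samples")
    if ploidies is None:
        ploidies = grid_ploidies(grid)
    alt = AlterationType(alteration)
    calls = call_matrix(grid, alt, thresholds, ploidies)
    cov = grid.covered
    pos = lab[None, :] & cov
    neg = ~lab[None, :] & cov
    a = (calls & pos).sum(axis=1)
    c = pos.sum(axis=1) - a
    b = (calls & neg).sum(axis=1)
    d = neg.sum(axis=1) - b

    records = []
    for i, (chrom, lo, hi) in enumerate(grid.intervals):
        ai, bi, ci_, di = int(a[i]), int(b[i]), int(c[i]), int(d[i])
        n_pos, n_neg = ai + ci_, bi + di
        if n_pos == 0 or n_neg == 0:
            # one outcome group has no informative sample here
            freq_pos = ai / n_pos if n_pos else math.nan
            freq_neg = bi / n_neg if n_neg else math.nan
            records.append(
                AssociationRecord(chrom, lo, hi, alt.value, ai, bi, ci_, di,
                                  freq_pos, freq_neg, math.nan, 1.0,
                                  math.nan, math.nan, math.nan, False)
            )
            continue
        p = fisher_p(ai, bi, ci_, di)
        est, lo_ci, hi_ci = odds_ratio_ci(ai, bi, ci_, di, method=or_method)
        records.append(
            AssociationRecord(
                chrom, lo, hi, alt.value, ai, bi, ci_, di,
                ai / n_pos, bi / n_neg, ai / n_pos - bi / n_neg,
                p, est, lo_ci, hi_ci, not math.isnan(est),
            )
        )
    return records


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    cols = [f.name for f in dc_fields(AssociationRecord)]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)


def write_association_table(records: Sequence[AssociationRecord], path) -> None:
    """Tab-separated export of association records; round-trips through
    :func:`read_association_table`."""
    records_to_frame(records).to_csv(path, sep="\t", index=False, na_rep="nan")


def read_association_table(path) -> list[AssociationRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        for k in ("chrom", "start", "end", "a", "b", "c", "d"):
            d[k] = int(d[k])
        d["or_defined"] = bool(d["or_defined"])
        out.append(AssociationRecord(**d))
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional extra column)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


@dataclass(frozen=True)
class CandidateRegion:
    """A maximal run of adjacent qualifying segments for one alteration type."""

    chrom: int
    start: int
    end: int
    alteration: str
    peak_or: float
    min_p: float
    n_segments: int


def candidate_regions(
    records: Sequence[AssociationRecord],
    p_max: float = 0.05,
    or_min: float = 4.0,
) -> list[CandidateRegion]:
    """Merge adjacent segments with p < p_max and odds ratio >= or_min.

    Records must be position-sorted and of a single alteration type.
    Segments with an undefined odds ratio never qualify.  Runs break at
    chromosome boundaries and at any non-qualifying segment (coordinate
    gaps within a chromosome do not break a run: adjacency is adjacency in
    the scanned grid).
    """
    alterations = {r.alteration for r in records}
    if len(alterations) > 1:
        raise ValidationError(f"records mix alteration types: {sorted(alterations)}")
    regions: list[CandidateRegion] = []
    run: list[AssociationRecord] = []

    def close_run():
        if run:
            regions.append(
                CandidateRegion(
                    chrom=run[0].chrom,
                    start=run[0].start,
                    end=run[-1].end,
                    alteration=run[0].alteration,
                    peak_or=max(r.or_estimate for r in run),
                    min_p=min(r.p for r in run),
                    n_segments=len(run),
                )
            )
            run.clear()

    for r in records:
        qualifies = (
            r.or_defined and r.p < p_max and r.or_estimate >= or_min
        )
        if qualifies:
            if run and r.chrom != run[-1].chrom:
                close_run()
            run.append(r)
        else:
            close_run()
    close_run()
    return regions


def top_region(regions: Sequence[CandidateRegion]) -> CandidateRegion | None:
    """The strongest candidate: smallest min_p, ties broken by peak OR."""
    if not regions:
        return None
    return min(regions, key=lambda r: (r.min_p, -r.peak_or))


def write_candidate_bed(regions: Sequence[CandidateRegion], path) -> None:
    """BED export: name column carries the alteration type and peak OR,
    score column the -log10 of min_p (capped at 1000)."""
    lines = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
        score = min(1000, int(round(-10 * math.log10(max(r.min_p, 1e-100)))))
        lines.append(
            f"{r.chrom}\t{r.start}\t{r.end}\t{r.alteration};OR={r.peak_or:.3g};"
            f"p={r.min_p:.3g};n={r.n_segments}\t{score}\n"
        )
    with open(path, "w") as fh:
        fh.writelines(lines)
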