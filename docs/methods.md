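# Methods

## Input model and coordinates

The unit of analysis is a tumour genome described by absolute allele-specific
copy numbers: ordered autosomal segments carrying integer `(total_cn,
minor_cn)` with `minor_cn` the lesser homolog (`minor ≤ total − minor`;
a file row like `total=1, minor=1` is folded to `1m0` at parse time).
This is the output layer of purity/ploidy-aware callers; purity, probe
noise, and segmentation error are assumed resolved upstream. Sex chromosomes
are rejected: every statistic here is defined over the 22 autosomes.

Files follow the conventions of their formats — SEG-style segment tables are
1-based inclusive, arm definitions and bedGraph/BED outputs 0-based
half-open — while all internal coordinates are 0-based half-open. A bundled
hg19 arm table defines the 44 autosome arms (p ends at the centromere gap
start, q begins at its end); any alternative build can be supplied as a
4-column TSV.

Gaps inside a profile are treated as missing data: excluded from that
sample's length-weighted means and medians, and excluded sample-wise from
the denominator of any scanned segment the gap covers. Denominators
therefore vary segment by segment; this is the unbiased choice under
partial coverage, at the cost of slightly varying power along the genome.

## CNA typing

Nine alteration flags are evaluated per segment against fixed thresholds
(`ClassificationThresholds`), using strict inequalities exactly as the
definitions state them:

| type | condition | default |
|---|---|---|
| GAIN | total > 2 | copies per cell |
| LOSS | total < 2 | copies per cell |
| REL_GAIN | total > 1.25 × ploidy | ratio to sample average |
| REL_LOSS | total < 0.67 × ploidy | ratio to sample average |
| HOMDEL | total = 0 | |
| HIGH_GAIN | total > ploidy + 3 | copies above average |
| FOCAL_GAIN / FOCAL_LOSS | gain/loss on a segment < 1 Mb | caller-segment length |
| LOH | minor = 0 | includes homozygous deletions |

`ploidy` is the sample's average ploidy — the length-weighted mean total
copy number over covered autosomal bases — used as a real number without
rounding. Length weighting (rather than per-segment counting) is used for
every mean and median in the package because results must not depend on how
finely a caller happens to split identical-state runs; `average_ploidy` is
invariant under any such split. Focal calls use the length of the sample's
own segment, not the (shorter) union segment it projects onto.

Relative types are what make hyperploid genomes comparable to diploid ones:
in a duplicated genome at ploidy ≈ 4, a region at 2 copies is REL_LOSS
(2 < 2.68) but not LOSS, while a diploid genome's drop to 1 copy is both.
The dissociation experiment below demonstrates exactly this.

## Breakpoint-union scan

Association statistics need segments on which every sample is in one state,
so the genome is partitioned at the union of all samples' segment
boundaries. Properties guaranteed (and property-tested per base pair
against brute force): no union segment straddles any sample's breakpoint;
segments are disjoint, sorted, and cover exactly the base-pair union of
input coverage. Adjacent segments with identical state vectors are *not*
re-merged — the grid is a pure function of the breakpoint set, and every
per-segment statistic is constant under such merges anyway.

Each segment × alteration type yields a 2×2 table `a,b,c,d` =
(altered/disseminated, altered/not, unaltered/disseminated, unaltered/not),
excluding samples missing at that segment. The p-value is the two-sided
Fisher exact probability by point-probability summation (the scipy and R
`fisher.test` convention: the sum over tables with the observed margins
whose probability does not exceed the observed table's); conventions for
two-sided exact tests differ, so this one is stated explicitly and verified
in the tests against an independent enumeration oracle for every table with
n ≤ 30. P-values are reported unadjusted — the scan is a screening step
whose hits are meant for external validation — with Benjamini-Hochberg
adjustment available as an optional column.

Odds ratios default to the conditional maximum-likelihood estimate (CMLE)
under the noncentral hypergeometric model with its exact 95% interval,
which stays meaningful with empty cells (estimate 0 or ∞, one-sided finite
bound) as happens constantly in genome-wide scans of moderate cohorts. The
cross-product (sample) odds ratio with Haldane-Anscombe correction and
Woolf interval is retained for transparency. A zero row or column margin
leaves the odds ratio undefined and the record flagged.

**Discovery vs reporting.** A region is *discovered* when adjacent segments
pass the initial significance cut-off p < 0.05; the effect-size filter
(odds ratio ≥ 4, `candidate_regions`' default) is a *reporting* criterion
for nominating regions worth validating. The distinction matters
statistically: at a true odds ratio of 5.67 and group sizes 57/35, the
probability that a single segment's estimated OR clears 4 is only ~0.74
even without noise, so conditioning discovery on the OR filter would
discard a quarter of genuinely detected signals. The replicated recovery
experiments in `cnascan.validation` therefore localise by p-value
(`or_min=0`) and report OR with its interval.

Stratified analyses (stage subsets, MSS only, chemotherapy-naive) are plain
metadata filters applied before grid construction; no stratified test
statistic is computed.

## Dissemination labelling

A sample is disseminated if stage IV at diagnosis, or stage II–III with
distant recurrence within 5 years. Stage II–III samples without recurrence
are analysable only with follow-up beyond 5 years (shorter follow-up cannot
support a negative label; such samples are excluded with a warning).
MSI-Low behaves like MSS and is merged into it at parse time.

## Ploidy, WGD score, CIN, burden

The WGD score exploits two asymmetries of duplication histories: 4 copies
arise more often as 2+2 of both homologs (`4m2`) after a doubling than by
successive gains of one homolog (`4m1`), and 2-copy LOH (`2m0`) arises more
readily via doubling-then-loss than by two independent losses. Per arm, the
length-weighted medians of total and of minor copy number are taken
independently (each rounded to an achieved integer by construction; the
*lower* median on even-weight ties, making a 50/50 arm read as its less
altered state); the score is #{2m0, 4m2} − #{2m1, 4m1}, other states
contributing 0, uncovered arms skipped. The call threshold `score > 0` is
the natural separatrix of the ± construction; cohort score distributions
are strongly bimodal (see below) so the exact cut is uncritical, and it is
configurable.

Bimodality is quantified by a two-cluster separation index: the exact 1-D
2-means split minimising pooled within-cluster variance, scored as
|μ₁ − μ₂| / (s₁ + s₂). A single Gaussian scores ≈ 1.3 and a uniform ≈ 1.7
independent of scale; > 2 is read as clearly bimodal. Simulated mixed
cohorts score ≫ 2 (typically > 10).

CIN: ≥ 5 distinct chromosomes carrying an alteration ≥ 10 Mb, with
contiguous equal-state altered runs merged before the length test. Burden:
chromosomes affected and Mb altered, "altered" meaning any state ≠ `2m1`.
Whether copy-neutral LOH (`2m0`) counts as altered is genuinely ambiguous;
it is included by default — the broadest reading — with an
`include_cnloh=False` switch on both burden and CIN.

## Synthetic cohort generator

The generator emulates the two genome classes of colorectal cohorts:
*quiet* (MSI-like) near-diploid genomes with a Poisson(3) handful of
events, and *CIN-like* genomes with Poisson(8) events of which a
configurable fraction (default 0.4) first undergo a whole-genome doubling
`(t,m) → (2t,2m)`. Events are drawn from the minimal grammar that generates
all the arm states the WGD score distinguishes: single-copy gain (major
allele), single-copy loss, and copy-neutral LOH (minor allele replaced by
major); whole-arm with probability 0.45, otherwise sub-arm with
exponentially distributed length (mean 20 Mb, floor 0.5 Mb). Arms are
chosen uniformly. Group sizes default to 63 disseminated / 53 controls with
a 0.2 quiet fraction, echoing the case-control composition such scans are
run on; the WGD fraction reproduces a cohort in which roughly 40% of
CNA-rich genomes are hyperploid and scores split bimodally.

The planted lesion is a spike-in: carriers (Bernoulli per group, defaults
0.50 disseminated / 0.15 control on a chr1:0–27 Mb, 1p36-like interval)
lose one copy *relative to the current genome* — one physical copy in a
diploid (`2m1 → 1m0`: absolute loss, relative loss and LOH) and one per
haploid-equivalent in a duplicated genome (`4m2 → 2m1`: relative loss with
two copies retained). Background events are redrawn off the planted
interval, so the configured frequencies are the *observed* group
frequencies at the locus and the implied odds ratio
(0.5/0.5)/(0.15/0.85) = 5.67 is exact. Without this exclusion the
background's own relative losses dilute the locus and the experiment
measures generator noise rather than the scan.

Reproducibility: one seed per cohort; each sample gets a deterministic
substream (`SeedSequence.spawn` by sample index), so cohorts are
bit-identical across runs and robust to parallel iteration order.

What the generator does **not** emulate: probe-level noise, segmentation
error, purity/subclonality (inputs are exact integer states with full arm
coverage), recurrent locus-specific alterations (background is uniform
across arms), and correlated event histories. Passing recovery experiments
therefore show the *scan's* statistical behaviour under clean inputs, not
robustness to caller error.

## Replicated validation experiments and problem sizes

`cnascan.validation` runs four experiments end to end through the public
pipeline (sizes chosen to make each experiment's Monte-Carlo error small
relative to what it checks):

- **Planted-lesion recovery** — 100 replicates of a 57/35 CNA-rich cohort.
  The top discovery region overlaps the planted interval in ≈ 92% of
  replicates, essentially the exact power of Fisher's test at these sizes
  and frequencies (0.939, computed by binomial-weighted enumeration) minus
  a ~2% chance that a random disseminated-only background pattern outranks
  the lesion; the exact CMLE interval covers the planted odds ratio in
  ≈ 95–97% of replicates. The background event rate (8 per CIN genome) was
  fixed alongside this experiment: much higher rates breed chance
  arm-level patterns that outrank a true signal of this size, which is a
  property of screening scans generally, not of this implementation.
- **Null calibration** — 20 replicates × ~1,150 segments (25 samples per
  group at an elevated event rate of 25). The per-segment rejection
  fraction at the 0.05 level is ~0.003–0.008: exact tests on discrete 2×2
  tables are conservative.
- **WGD recovery** — one 250-sample mixed cohort: score > 0 agrees with the
  simulated duplication indicator for every sample in practice (≥ 95%
  asserted), and the score distribution's separation index is ≫ 2.
- **Relative/absolute dissociation** — 20 replicates, 100 per group, all
  genomes duplicated: the planted `4m2 → 2m1` lesion is discovered by every
  REL_LOSS scan and by no absolute-LOSS scan — two copies remain, so there
  is nothing for an absolute threshold at 2 to see.

## Numerical and degenerate-input choices

- Weighted medians: lower median on even-weight ties (`searchsorted` on the
  cumulative weight at half the total).
- Empty profile, all-missing arm set, empty cohort: errors, not sentinel
  values. An arm with no coverage yields a missing state skipped by the
  score.
- A scanned segment where one outcome group has no covered sample gets
  p = 1 and an undefined, flagged odds ratio; undefined odds ratios never
  qualify for candidate regions.
- χ² tests refuse tables with a zero margin.
- Fisher p-values and CMLE intervals are memoised on the 2×2 counts: scans
  of a cohort share margins across thousands of segments, so the cache
  collapses most of the cost.
- Candidate-region runs break at chromosome boundaries and at any
  non-qualifying segment; coordinate gaps between consecutive grid
  segments do not break a run (adjacency is grid adjacency).

## Known limitations

- The scan treats segments marginally; no spatial smoothing, no
  multiple-testing control by default, and no joint model across alteration
  types (absolute loss, relative loss and LOH overlap by construction).
- Arm-median states discard sub-arm structure; a half-arm `2m0` next to
  half-arm `2m1` reads as one or the other, never both.
- The CIN rule and burden depend on the "altered = ≠ 2m1" reading; genomes
  judged against a different normal baseline (e.g. constitutive trisomy)
  are out of scope.
- Logistic-regression-style covariate adjustment and survival modelling are
  deliberately absent; the pipeline tests marginal association with a
  binary dissemination label.
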