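# Methods

## Setting and data model

The pipeline operates on a normalized beta-value matrix β (probes ×
samples, β ∈ [0, 1]) from a methylation array, a sample sheet mapping
samples to subjects, outcome groups (converter / nonconverter) and
timepoints (M0 baseline, MF follow-up), and a per-probe annotation (hg19
chromosome, 1-based position, UCSC gene symbols, QC flags). Normalization,
cell-mixture adjustment and batch correction are assumed done upstream.
Missing betas are explicit (`NA` in files, NaN in memory); any statistic
drops a probe's missing contributions and masks the result when too little
data remains (details per operation below).

## Quality filtering

Sample rule: a sample is excluded when strictly more than 4500 CpGs
(about 1% of a 450K array) have detection p ≥ 0.05. The count threshold is
absolute and configurable; the p cut-off is inclusive.

Probe rules, applied to the samples retained by the sample rule, with one
primary reason recorded per probe in this precedence:

1. *detection* — detection p ≥ 0.05 in at least one sample (inclusive, one
   sample suffices);
2. *beadcount* — beadcount < 3 in ≥ 5% of samples. The fraction is
   compared exactly (count · denominator ≥ numerator · n via
   `fractions.Fraction`), so 2/40 = 5.0% excludes and no floating-point
   boundary artifact can flip the decision;
3. flags — sex-chromosome probes (derived from the annotation chromosome),
   SNP probes, probes with a SNP at the CpG, cross-reactive probes;
4. *unannotated* — probes absent from the annotation are excluded with
   their own reason rather than silently dropped.

Computing the beadcount fraction over post-sample-QC samples mirrors the
sequential behavior of the standard array-QC toolchains. Filtering is
idempotent, and lowering the detection threshold can only shrink the
retained set (both properties are tested). Identity checks that need raw
array internals (sex and genotype concordance) are exposed as a no-op hook
only.

## VMP detection

For every subject with exactly one sample at each timepoint,
Δβ = β(MF) − β(M0) per probe. Within an outcome group the per-probe
statistic is, by default, the absolute group median, |median(Δβ)|
(`abs_of_median`). The alternative reading of "median absolute
difference", median(|Δβ|) (`median_of_abs`), is also implemented because
the two differ exactly when changes are two-sided: for Δβ =
{−0.2, 0, +0.2} the first is 0 and the second 0.2. The mode used is
written into every result row. Even-sized groups use the mean-of-middle-two
median. A probe is a VMP when the statistic ≥ 0.1, inclusive — 0.10
qualifies, 0.099 does not. The 10% level is the conventional threshold at
which Illumina methylation differences are considered biologically
meaningful and unlikely to be technical.

Missing policy: a probe needs ≥ 2 non-missing deltas in the group and at
most 20% of the group missing; otherwise its statistic is missing (and
never a VMP), which avoids medians driven by a couple of subjects.

The statistic is invariant to adding a constant to both timepoints of
every sample (only change matters) and, in `abs_of_median` mode, to
negating all deltas.

## Epimutation detection

**Variance scan.** Per probe and timepoint, F = s²_conv / s²_nonc with
unbiased (n−1) variances; two-sided p = 2·min(P(F ≤ f), P(F ≥ f)) capped
at 1 under F(n_conv−1, n_nonc−1). Degenerate probes — fewer than two
non-missing values in a group, or a zero sample variance — are flagged
(`constant` probes get p = 1, single-zero-variance probes the p → 0
limit) and excluded from multiple-testing correction. Benjamini–Hochberg
FDR is computed per timepoint across all non-degenerate probes
(`statsmodels` step-up; cross-checked in the tests against an independent
hand-rolled implementation). At the design sample sizes (14 vs 25) the
test is exactly calibrated under a normal null; the suite verifies a
Monte-Carlo type-I error of 0.05 ± 0.005 at 10⁵ replicates.

**Candidate filters.** A probe is a candidate epimutation locus when

1. FDR-significant at MF (q < 0.05) with converters the higher-variance
   group,
2. the converter variance strictly increased from M0 to MF (raw
   comparison, not itself significance-tested), and
3. it is converter-specific.

Converter specificity is ambiguous in the underlying design; two readings
are implemented and labelled as interpretations. Default
(`between-group`): exclude probes that are FDR-significant at either
timepoint with the *non-converters* the higher-variance group. Optional
(`longitudinal`): exclude probes whose within-non-converter M0-vs-MF
variance F-test is FDR-significant.

**Calling.** At each candidate probe, each converter's deviation is its
beta minus the converter-group median beta at that timepoint (the group
must have ≥ 3 members; by construction the deviations of a probe
re-median to zero). A call is emitted when |deviation| > 0.10 **strictly**
— a deviation of exactly 0.10 is not a call. The strictness is fixed by
the packaged worked example, where two cells printed as exactly 0.10 are
not treated as calls. Direction is hyper (positive) or hypo (negative).
Group medians can alternatively be taken over all samples
(`compute_deviations` is group-parameterized); the packaged example uses
the converter-only median, matching its published tabulation.

**Summaries** count calls per subject over the full subject list
(zero-call subjects included) and, for probes with ≥ 2 carriers, whether
all carriers share a direction.

## Packaged worked example

`methvar.datasets.load_epimutation_panel()` returns the published
25-CpG × 14-converter deviation panel (before and after transition, values
at 2-decimal printed precision) plus the probe → gene map with FDR-adjusted
variance-test p-values. Running the strict caller on the after block
yields 12 called CpGs and 16 calls with per-subject histogram
{0: 4, 1: 5, 2: 4, 3: 1}; four CpGs have exactly two carriers, three
shared-hyper and one shared-hypo. Comparisons against the panel are made
at its printed precision (±0.005). Whether the original 10% rule was
applied to rounded or unrounded deviations is unknowable from the printed
table; all fixture-based checks use the printed values. The panel's
per-subject antipsychotic-introduction marks could not be recovered from
the available text layout and are not packaged; nothing in the pipeline
depends on them.

## Synthetic cohorts

`simulate_cohort` generates the study conditions: n_conv = 14 vs
n_nonc = 25 subjects, two timepoints, n_probes CpGs. Per probe a baseline
mean is drawn from a two-mode mixture (low ≈ 0.1, high ≈ 0.85, equal
weight, logit-scale jitter sd 0.5), reproducing the bimodal marginal of
array betas. Per subject, M0 betas are inv-logit(logit(m) + e) with
e ~ N(0, noise_sd); MF adds drift d ~ N(0, drift_sd) on the same logit
scale. Logit-normal noise was chosen over Beta noise because it keeps the
support automatic and the spread specification single-parameter, with the
realistic property that beta-scale spread shrinks near 0 and 1
(≈ sd · β(1−β) by the delta method — a relation the tests verify against
the realized mean |Δβ| at 10⁴ probes). Defaults noise_sd = drift_sd =
0.02 (logit scale, i.e. ≤ 0.005 on the beta scale at mid-methylation)
describe a quiet technical-replicate-like null.

Planted truth: VMPs add a beta-scale shift (default 0.15) to every member
of the target group at MF; epimutations add a beta-scale offset (default
0.25) to a single (probe, subject) at MF. Plants are directed toward
mid-methylation so the full magnitude lands inside [0, 1]; overshooting
plants are clipped to [1e−6, 1 − 1e−6] and recorded in the truth table.
Applying plants at MF only matches the variance-increases-with-time
premise of the candidate filters. Optional QC corruption (detection-p
failures, low beadcounts) is independent of the methylation values so QC
tests do not entangle with the statistics tests. Everything is a
deterministic function of the seed.

What the simulator does *not* emulate: Infinium I/II probe-type chemistry,
cell-composition mixtures, batch structure, spatial correlation along the
genome, or heavy-tailed population outliers. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
stated noise model, not performance on raw clinical data.

## Problem sizes and numerical choices

Recovery tests run at 10⁴ probes with the 14 + 25 design (seconds on one
CPU); the F-test calibration uses 10⁵ Monte-Carlo replicates. Betas read
from files may stray from [0, 1] by at most 1e−9; beyond that the cell is
rejected by name. Statistic ties in VMP ranking break lexicographically by
probe id. BED export converts 1-based annotation positions to 0-based
half-open single-base intervals and scales scores into [0, 1000]
(statistics in [0, 1] are multiplied by 1000; otherwise min-max scaled);
unannotated probes go to a rejects sidecar. Under a complete null the
BH procedure still rejects somewhere in about 5% of cohorts (FDR = FWER
at the full null), so "no candidates on a null cohort" is a
typical-seed expectation, not a guarantee.

## Limitations

The F-test is highly sensitive to non-normality; on real betas (bounded,
sometimes trimodal) its nominal calibration degrades, which is one reason
the candidate filters and the 10% deviation rule sit downstream of it.
Group sizes of 14 vs 25 give the scan limited power for subtle variance
changes; the detectors target large, individual-level effects. The
converter-specificity filter is an interpretation (see above) and both
readings are exposed rather than adjudicated.
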