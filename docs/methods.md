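# Methods

This document records the statistical procedures implemented in
`qpcrdiff`, the conventions chosen where the underlying methods admit
more than one reading, and the known limitations.

## Input model

A Ct table holds one cycle-threshold value per (sample, gene). Two
layouts are read, each in CSV, TSV (`.txt`) or Excel:

- **wide** — columns: sample, group, then one column per gene;
- **long** — exactly four columns: sample, group, gene, Ct.

Policies:

- Non-numeric Ct tokens (blank, `Undetermined`, `>40`, …) and
  negative values become missing, with a warning. No imputation is
  performed anywhere in the pipeline.
- Duplicate gene columns are rejected (files are parsed headerless so
  duplicates cannot be silently renamed).
- Repeated sample rows are technical replicates and are collapsed by
  the **geometric mean** of Ct before any analysis. Collapsing is
  idempotent and order-invariant. Replicates with conflicting group
  labels are an error.
- Excel files may carry a second sheet of per-sample categorical
  metadata; any metadata column can serve as the grouping variable
  (`variable=` in the API, `--variable` on the CLI).

## Housekeeping stability

Candidate normalizers are scored with a model-based variance
decomposition (the NormFinder family of estimators). For gene *i* and
group *g* with *k* candidate genes and *G* groups, the per-group
residual variance after two-way (gene × sample) centring estimates
the intragroup variation; the unbiased estimator is

σ̂²ᵢg = (mᵢg − Ŝg/k²) · k/(k−2),  Ŝg = k/(k−1) · Σᵢ mᵢg,

where mᵢg is the mean squared two-way-centred residual. With k = 2
the correction is undefined and the raw residual variance is used.
The intergroup deviation dᵢg is the two-way-centred gene × group mean,
shrunk toward zero through a common variance component

γ̂² = max( Σ d²/((k−1)(G−1)) − mean(σ̂²/n), 0 ),

and the stability value is

ρᵢ = mean over groups of [ |dᵢg·γ̂²/(γ̂²+σ̂²ᵢg/ng)| + √((σ̂²ᵢg/ng)·γ̂²/(γ̂²+σ̂²ᵢg/ng)) ].

Conventions:

- Ct values are used directly as the log-scale input; the sign flip
  relative to log quantity does not affect a variance-based score.
- With γ̂² = 0 the bias term vanishes and the score falls back to the
  mean standard error √(σ̂²ᵢg/ng), keeping both regimes on the same
  scale.
- A single group reduces to the intragroup standard deviation.
- Pair stability scores the averaged pair ((dᵢ+dⱼ)/2 variance
  (σ²ᵢ+σ²ⱼ)/4) so averaging two genes with opposite group bias cancels.
- Missing values: each group uses its complete-case rows across all
  candidates; a group with fewer than 2 complete samples is dropped
  from the computation for **all** candidates (keeping the comparison
  fair), with a warning.
- Ties on the minimal stability value resolve to the
  lexicographically first gene or pair, logged.
- These estimator constants were derived from the published model
  (expected residual sums of squares under the two-way layout), not
  validated formula-by-formula against any reference implementation;
  the property suite (shift/relabel invariance, monotonicity in noise
  and in planted bias, ranking recovery) is the acceptance evidence.

`select_housekeeping` uses the best **pair** when two or more
candidates are given, the single gene as-is when one is given, and
searches every gene (with a warning) when no candidate list is given.

## Normalization (Livak)

Per sample, HKmean is the **arithmetic mean of the housekeeping Ct
values** — equivalent to the geometric mean of the linear quantities
under the method's ~100 % efficiency assumption — and

−ΔCt(target) = HKmean − Ct(target).

A −ΔCt is missing iff the target Ct or any housekeeping Ct is missing
for that sample. All housekeeping *candidates* (chosen or not) are
excluded from the target matrix, so 68 genes with 5 candidates yield
63 targets. −ΔCt is invariant to adding a constant to every Ct.

Relative expression for one gene against a reference group is
computed on the fold scale:

2^(−ΔΔCt)ₛ = 2^(−ΔCtₛ) / median over reference samples of 2^(−ΔCt),

so the reference-group median is **exactly** 1 (anchoring on the −ΔCt
median first and exponentiating after would miss exactness for
even-sized groups, since 2^median(x) ≠ median(2^x) in general).

## Group comparison

- **Normality**: per-group one-sample two-sided Kolmogorov–Smirnov
  test against a normal with the group's plug-in mean and SD
  (ddof = 1). Groups with fewer than 3 values get a missing p-value
  with a warning. A degenerate (zero-SD) group counts as non-normal.
- **Routing** (`test="auto"`): if any selected group has KS p < 0.05
  the gene is compared by Mann–Whitney; otherwise by Student's
  (equal-variance) t-test.
- **Mann–Whitney**: exact two-sided p when the pooled sample size is
  ≤ 25 and there are no ties; otherwise the normal approximation with
  continuity correction. The exact branch matches exhaustive
  label-permutation enumeration (verified for all splits with
  n₁+n₂ ≤ 8).
- **Fold change**: FC = 2^(median(−ΔCt, group A) − median(−ΔCt, group B)).
  Medians are robust to the heavy tails typical of single-cell data;
  FC is antisymmetric under group swap (FC_AB = 1/FC_BA).
- **Stars**: `ns` (p ≥ 0.05), `*` (p < 0.05), `**` (p ≤ 0.01),
  `***` (p ≤ 0.001), `****` (p ≤ 0.0001); the strongest applicable
  label wins.

## Volcano screening

Every target gene is tested between two groups with a single test
family per run (default Mann–Whitney). P-values are
Benjamini–Hochberg adjusted across the run's gene set (missing
p-values pass through without consuming a rank; the implementation is
verified against the brute-force step-up definition). Classification
against thresholds (defaults FC > 2, p < 1×10⁻⁴, both strict
inequalities):

- `significant` — |log2 FC| above threshold and p below threshold;
- `fc_only`, `p_only`, `ns` otherwise.

Genes testable in neither group (all missing, or a group below the
minimum size) are flagged `untestable` and classified `ns`.

## Differential correlation

For each group, a gene × gene correlation matrix is computed on
pairwise-complete observations (pairs with n < 3 stay missing):

- **Method choice** (`auto`): Pearson if every gene passes the KS
  normality check in every selected group, otherwise Spearman. One
  method per run, never mixed across groups.
- **Spearman p**: exact over the permutation null for n ≤ 9 with no
  ties (null distributions cached per n), Student-t approximation
  otherwise. The exact branch matches exhaustive permutation
  (verified for n ≤ 6).
- **Gating**: coefficients with p > α (default 0.05) are set to 0;
  missing coefficients stay missing. Gating encodes "no reliable
  correlation" as the zero point of the rewiring scale.

The rewiring score for a gene pair between groups A and B is

dR-val = |r_gated(A) − r_gated(B)| ∈ [0, 2],

reported for all gene pairs against a reference group (or for all
group pairs with `all_pairs=True`), sorted descending with missing
values last. All matrices entering one dR-val table must share the
same method and α.

## Synthetic data generator

`generate_dataset` plants known structure on the −ΔCt (log2) scale
and maps it to Ct through simulated housekeeping genes plus a shared
per-sample loading effect, so Livak normalization inverts the
construction exactly in the noise-free limit:

- per-gene, per-group mean shifts (differential expression);
- housekeeping candidates with chosen SD and group shifts (stable and
  deliberately unstable candidates);
- per-group target Pearson correlations for disjoint gene pairs via
  bivariate normal noise — note the planted value is the *latent*
  correlation; housekeeping measurement noise adds a small shared
  component after normalization that attenuates it slightly;
- optional right-skewed (median-centred exponential) noise per
  gene × group to break normality;
- missing-completely-at-random cells and technical replicates with
  jitter.

`example_dataset` is a seeded 68-gene × 328-sample four-group replica
of a large single-cell panel: five housekeeping candidates A–E (B and
E planted stable), 12 genes differentially expressed between Groups 1
and 2, a planted PCNA–KDM5B correlation flip between Groups 1 and 3,
and a skew-contaminated gene (AKT1). The design constants (group
sizes, effect sizes, noise SDs) are the generator's study conditions,
fixed up front; validation tolerances in the test suite are stated
against the planted truth, not fitted to outcomes. It is synthetic
data: it reproduces the *structure* of such an experiment, not any
original measurements.

## Limitations

- PCR efficiency is assumed ~100 % (Livak); no Pfaffl correction.
- Stability scoring implements the variance-decomposition criterion
  only; geNorm/BestKeeper-style criteria are out of scope.
- No multiple-testing correction across *group pairs* in the per-gene
  pairwise comparison table (BH is applied across genes in the
  volcano screen).
- dR-val has no significance test of its own; it is a ranking score,
  and gating at α is the only inferential filter.
- Complete-case handling throughout; heavy, non-random missingness
  will bias group medians and correlations.
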