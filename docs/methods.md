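# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the design decisions behind `wntsig`.

## Signature derivation

A differential-expression record carries a gene identifier, a log₂ fold
change (Wnt-positive over Wnt-negative) and a multiple-testing-adjusted
p-value.  The DEG call is `padj < 0.05` (strict inequality) together with
`|log2fc| >= 1` (inclusive); both thresholds are configurable
(`--padj-max`, `--lfc-min`).  Records with missing `padj` are dropped with
a warning — DE tools emit NaN for rows removed by independent filtering,
which are by definition not significant calls.  Duplicated gene
identifiers within one table are a hard error, not a silent deduplication:
they indicate upstream corruption.  Gene matching is exact string equality
after whitespace trimming; no symbol-alias resolution is attempted, and
identifier-convention mismatches surface through the coverage statistics
of the scoring stage rather than through guessed mappings.

Signed intersection partitions the genes shared by two filtered tables
into consistently up (positive fold change in both), consistently down,
and opposite-sign sets; the partition is checked as a class invariant.  A
fold change of exactly zero among shared significant genes cannot occur
after filtering at `lfc_min >= 1`, so the corresponding error branch only
guards misconfigured thresholds.  The four-way consensus keeps genes
significant with the same sign in all four comparisons.  Each comparison
additionally yields three signatures — full, up-only, down-only — the
direction-restricted splits being the gene sets ranked for subtype
discrimination.

## GES scoring

The GES score of a sample is the unweighted mean of the signature genes'
expression values in that sample.  Up- and down-regulated members are
pooled without sign weighting, because the score is defined as a plain
average over "all genes within a given signature"; the down-weighted or
directional variants common elsewhere (ssGSEA, signed z-combinations) are
deliberately out of scope.  Scores inherit the input scale: the package is
unit-agnostic, expects normalized log-scale expression, and records the
caller's declared unit in the output metadata rather than transforming
anything.  An optional per-gene z-scoring flag exists (off by default).
Signature genes missing from the cohort are dropped with a warning and
reported as `n_used` / `coverage`; a signature with zero overlap is an
error.  This coverage-first policy is also how the pipeline accounts for
signature sizes shrinking when a cell-line-derived gene list meets a
cohort with a different measurable-gene universe.

## Subtype discrimination

One-way ANOVA is computed from the standard sum-of-squares decomposition
(`MSE = SS_within/(N−k)`, `F = MS_between/MSE`, p from the F(k−1, N−k)
upper tail).  Pairwise contrasts use the Tukey–Kramer studentized-range
statistic

    q_ij = |ybar_i − ybar_j| / sqrt((MSE/2)(1/n_i + 1/n_j)),

which reduces to Tukey's equal-n HSD statistic and satisfies the two-group
identities `q = sqrt(2)|t|` and `F = q²/2` used as cross-checks in the
test suite.  Adjusted p-values are the upper tail of the studentized-range
distribution with k groups and N−k degrees of freedom, evaluated through
`scipy.stats.studentized_range` (a numerical implementation of the
standard double-integral definition, no lookup tables); the tests verify
these tails against a direct Monte-Carlo simulation of the range-over-
scaled-χ statistic at q ∈ {2, 3, 4} within three Monte-Carlo standard
errors, and against statsmodels' Tukey HSD as an independent oracle.

A gene set's discriminatory power for a focal subtype (default MLIA) is
summarized by the minimum q over the focal-vs-other pairs, and gene sets
are ranked by that minimum, largest first.  The published reference table
of pairwise statistics does not define which quantity "HSD value" denotes;
the q statistic is implemented as the canonical choice, and the pairwise
output TSV additionally exposes the signed mean difference and
q/q_crit(α) so users preferring those scales can read them off directly.
Ranking ties are broken by the second-smallest focal q (larger wins), then
lexicographically by name, making the ranking deterministic.  Significance
is reported at the inclusive threshold p ≤ 0.01, with raw p always
emitted.

## Meta-statistics

Stouffer's unweighted method combines k one-sided p-values as
`Z = Σ Φ⁻¹(1−p_j)/√k`, `p = 1 − Φ(Z)`.  Inputs are clamped to
[1e−15, 1−1e−15] before the quantile transform because enrichment tools
emit p = 0 for saturated terms.  The combination is applied to
already-adjusted p-values — statistically unconventional, but that is the
quantity the upstream enrichment exports carry, and re-deriving raw
p-values is not possible from those exports.  No re-adjustment of the
combined p-values is performed.  Shared-term ranking restricts to the
term-identifier intersection of all condition tables and sorts ascending
by combined p with term-id tie-breaks.

Pearson correlation between signature score vectors is pairing-aware:
Series inputs must carry identical sample-identifier sets and are aligned
by identifier; constant vectors and vectors shorter than 3 are rejected.

## Gene clustering (H-clusters)

Gene distance is centered Pearson, `d = 1 − r`, in [0, 2].  Ward linkage
is implemented directly via the Lance–Williams recurrence applied to
**squared** input distances — the "Ward.D2 on provided distances" dialect —
because 1 − r distances are not Euclidean-embeddable in general and the
dialect must therefore be stated, not assumed.  Merge heights are square
roots of the updated squared criterion, which keeps the dendrogram
monotone; on genuinely Euclidean input the tree coincides with SciPy's
`linkage(..., method="ward")` (verified in tests).  Agglomeration ties are
resolved by merging the pair with the lexicographically smallest cluster
identifiers, so trees are deterministic given input order; the extracted
partition itself is input-order-invariant when no ties occur.

The cut criterion behind published H1/H2 cluster counts is not
reconstructable, so the cut is an explicit parameter: default k = 2, or
`--auto-k` choosing k ∈ [2, 10] by maximal mean silhouette width on the
gene distances (scikit-learn, precomputed metric); the chosen k and the
selection mode are logged and written to the manifest.  Clusters are
labeled H1..Hk by descending mean expression of their genes in the focal
subtype, so H1 is always the most focal-elevated module.  The complexity of
the direct agglomeration is O(n³) in the number of genes, which is ample
for signature-sized inputs (tens to a few thousand genes).

## Synthetic-data model

The generator's defaults are the study conditions, so that the pipeline's
headline counts are recoverable end to end:

* **DEG tables.**  Four tables (2 cell lines × 2 serum conditions) over
  5 000 genes.  Planted categories: 42 consensus-up and 13 consensus-down
  genes (significant with consistent sign in all four tables);
  condition-consistent genes beyond the consensus (low serum: 63 up,
  20 down; standard: 53 up, 25 down); opposite-sign shared genes (78 low,
  114 standard, split evenly between the two orientations); and
  cell-line-specific genes (543 / 1 191 / 678 / 1 296), leaving the rest
  null.  These counts make the filtered tables reproduce per-comparison
  totals of 759 / 1 407 / 925 / 1 543 DEGs, pairwise overlaps of 216
  (138 consistent: 105 + 33; 78 opposite) and 247 (133 consistent:
  95 + 38; 114 opposite), and a 55-gene consensus.  Significant calls draw
  `padj ~ U[1e−6, 0.049]` and `|log2fc| ~ U[1, 4]` with the planted sign;
  null calls draw `padj ~ U[0.06, 1]` (always failing the p cut) and
  `log2fc ~ U[−0.99, 0.99]`.  Adjusted p-values are generated directly
  rather than via a DE model: the pipeline consumes DEG tables, so only
  their schema and threshold behavior need emulating.  The published
  per-table up/down splits are *not* planted, because the reported splits
  for the standard-serum MDA-MB-231 comparison (587 + 388) are internally
  inconsistent with its reported total (925); table-specific genes get
  random signs instead.
* **Cohort.**  Log-expression is Gaussian:
  `x[g,s] = mu_g + delta·dir(g)·1[subtype(s)=focal] + sigma·(sqrt(rho_g)·
  z[block(g),s] + sqrt(1−rho_g)·eps[g,s])`, with per-gene baselines
  `mu_g ~ N(6, 2)` (a log₂-expression-like range), `dir = +1/−1/0` for
  signature up / down / background genes, and equicorrelated blocks
  (within-block gene–gene correlation `block_rho`) formed by dealing
  signature genes into contiguous chunks.  Defaults: the published subtype
  sizes LAR 137, MLIA 121, BLIA 199, BLIS 242 (n = 699), focal subtype
  MLIA, `delta = 0.5`, `sigma = 1`, no blocks.  A Gaussian model (not
  negative-binomial counts) is used because the scoring stage operates on
  normalized expression and Gaussian noise makes the oracle calculations
  closed-form; simulating read counts or library-size effects is a
  non-goal.  Consequently, passing recovery tests demonstrates the
  correctness of the statistics under their own assumptions — not
  robustness to count noise, normalization artifacts, batch structure or
  heavy tails in real cohorts.
* **Enrichment pair.**  Two condition tables sharing exactly `n_shared`
  term ids, of which `n_strong` (default min(10, n_shared)) draw
  `padj ~ U[1e−10, 1e−6]` in both conditions and therefore dominate the
  combined ranking.

One `numpy` Generator seeded from `SimConfig.seed` drives each generator,
with draws in a fixed documented order, so identical configs give
byte-identical written outputs across runs.

## Problem sizes and calibration checks

The recovery analyses use 100 replicates at `delta = 0.5·sigma` (all-three
focal contrasts significant and focal-top-mean rates), 200 null replicates
at `delta = 0` (the all-three-significant event stays ≤ 2%), 20 seeds for
exact consensus recovery, and a 24-gene two-block cohort at
`block_rho = 0.8` for adjusted-Rand-index cluster recovery — sizes chosen
to give stable rates while keeping the full suite fast on one CPU.  With
55 signature genes at `sigma = 1`, the per-sample score SD is ≈ 1/√55 ≈
0.13, so a 0.5·σ planted shift corresponds to focal-vs-other q values in
the tens — comfortably beyond the p ≤ 0.01 studentized-range threshold at
these group sizes, which is why the power criterion is expected to sit at
100%.

## Numerical and formatting choices

Floating-point file output uses six significant digits; JSON is written
with sorted keys.  Tests compare floats at relative tolerance 1e−6 or
better except where a quantity is a count (exact).  All sets are sorted
before writing, so outputs are independent of Python hash randomization;
`run-all` twice on the same inputs is byte-identical.

## Known limitations

* GMT files carry no direction information; signatures read from GMT load
  all genes as "up", which is irrelevant for GES scoring (directions are
  pooled) but means a GMT round-trip loses the up/down split — use the
  two-column TSV format to preserve it.
* The studentized-range p-values assume homoscedastic groups, as does the
  underlying ANOVA; no Games–Howell-style correction is offered.
* The published cohort behind the reference HSD table is not public, so
  those statistics are consumed as worked-example inputs; they cannot be
  recomputed from expression data here.
* Enrichment itself (GO/KEGG/GSEA) is out of scope; the pipeline only
  ranks term tables produced elsewhere.
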