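# Methods

This note documents the statistical procedures implemented in `metsig`, the
generative model behind its synthetic cohorts, and the numerical
conventions and open design choices the code commits to.

## The analysis

### Paired differential expression

Input TPM matrices are quantile normalized (all samples forced onto the
common distribution given by the row means of the column-sorted matrix;
tied values within a column receive the mean of the reference values their
rank range spans) and transformed as log2(TPM + 1). For each gene, the
per-patient difference d_i = metastasis_i − primary_i is tested against
zero with a one-sample t-test on n − 1 degrees of freedom; pairs with a
missing value are dropped gene-wise. No per-gene multiplicity adjustment is
applied; instead the aggregate false-discovery rate at threshold α is
estimated as (N · α) / n_significant, the expected chance count over the
observed count. All threshold comparisons in the package are strict
(p < α, score < −0.75, fraction > 0.10, expression < −0.5), matching the
conventions the constants are quoted with.

Degenerate genes whose differences are all identical get p = 1 when the
common difference is zero and the smallest representable positive p (with
t = ±∞ as a flag) otherwise.

### Essentiality partition and contingency statistics

A gene is called essential in a cell line when its gene effect score is
strictly below −0.75; a gene is essential overall when more than 10% of the
lines assayed *for that gene* are below threshold (the denominator is the
per-gene assayed count, not the nominal panel size — a choice that matters
only when scores are missing). Metastasis-high genes are partitioned into
essential (fraction > 0.10), nonessential (zero lines below threshold) and
intermediate (the rest); classes partition the input set by construction.

Set overlaps are quantified on an explicit 2×2 table over a stated
universe: expected overlap E = |A||B|/N (reported raw and rounded
half-away-from-zero), Pearson chi-square with df 1 and **no** Yates
continuity correction (the expected cells in this application are far above
5, where the correction only biases the statistic), and a one-sided Fisher
enrichment p from the hypergeometric upper tail P(X ≥ a). The Fisher path
is verified in the test suite against exhaustive hypergeometric enumeration
for every 2×2 table with N ≤ 30. Odds ratios with a zero off-diagonal cell
are reported as infinite and flagged rather than corrected.

### Tissue-confound diagnostics

The normal-tissue contrast pools all non-breast tissues into a single
comparison group and uses Welch's unequal-variance t-test, which is robust
to the extreme group-size and heterogeneity imbalance of a
one-tissue-vs-all design. Immune-infiltrate scores are per-patient means of
paired log2 fold changes over marker gene sets (supplied as GMT, not
hard-coded), tested against zero. Per-site summaries report, for each
metastasis, the mean paired fold change over a gene set, with 5/25/50/75/95%
quantiles per biopsy site; the across-site variance of the per-site median
is the summary used to contrast the nonessential set (site-driven) with the
essential set (site-homogeneous).

### Compendium normalization and replication

Each external paired study is normalized by centering every metastasis
profile on its paired primary (primaries become exactly zero) and dividing
all centered values by the study SD computed jointly across the centered
metastasis and primary entries — the zeros contribute to the denominator.
This renders differential expression unitless so that studies on different
platforms can be pooled. The replication test is then a pooled one-sample
t-test of the centered values across all studies' pairs; a gene replicates
at p < α with positive mean. Pooling (rather than per-study meta-analysis)
is the direct reading of the normalization's purpose; the per-profile-SD
variant of the scaling is available behind a flag
(`center_and_scale(..., per_profile_sd=True)`).

### Signature t-score and survival association

Profiles are standardized gene-wise to standard deviations from the median
(zero-SD genes dropped with a logged count; sample SD, n − 1 denominator
everywhere, for consistency with the t statistics). The signature t-score
of a profile is the two-sample t-statistic comparing the signature genes
against all other genes — Welch by default, since a few-hundred-gene
signature is compared against a many-thousand-gene background of different
variance; the pooled-variance variant is a flag. For bidirectional
published signatures the comparison is up-genes vs down-genes.

Survival association uses Cox proportional hazards (lifelines, Efron tie
handling, Wald p) with the score as a continuous covariate, optionally
jointly with covariates such as a proliferation marker; and a k-sample
log-rank test on low/intermediate/high groups cut at score tertiles
(33.3/66.7% quantiles — the cutpoints are a free choice and configurable).
The random-signature null draws n (default 100) gene sets of the same size
uniformly without replacement from the scored matrix's genes and records,
per draw, the SD of the scores across profiles (coordinate expression) and
the univariate Cox p, plus the actual signature's rank on both axes.

Genome-wide per-gene Cox screening (for the prognosis-gene overlap) uses
the partial-likelihood score test of β = 0, computed in closed form and
vectorized over genes (U = Σ_events (x − x̄_risk), V = Σ_events
Var_risk(x), z = U/√V, Breslow ties). A full per-gene Newton fit would be
thousands of independent model fits for the same screen; the score test is
asymptotically equivalent at the null, its z sign matches the fitted
coefficient's sign, and the suite cross-checks it against per-gene
lifelines fits on a sampled panel.

### Subtype assignment

From a labeled reference cohort, per-gene subtype means are centered on the
mean centroid (the unweighted mean of the subtype means, so each gene's
centroid row sums to zero). Query profiles are standardized to SD-from-
median within each (study, role) block, correlated (Pearson, over common
genes) with each centroid, and assigned the argmax subtype; ties break by
fixed subtype order with a warning, and original study annotation always
overrides an inferred label.

### Regulator enrichment

Gene upstream windows are strand-aware: [start − w, start) on the + strand,
[end, end + w) on the −, with w = 2,000 bp, 0-based half-open coordinates
(BED convention) and clipping at zero; a gene is a TF target when any of
that TF's binding sites has nonempty intersection with the window. A
strand-naive mode (always [start − w, start)) exists for sensitivity
checks. Knockdown targets are genes with standardized expression strictly
below −0.5 in the knockdown's profile. Enrichment of a query set in any
named collection is the hypergeometric upper tail over an explicit,
reported universe — the default universe is the genes measured in the
dataset that produced the query. Multiway intersections of 2–4 sets return
the full disjoint membership partition of the union.

### Single-cell scoring

Counts matrices keep genes with strictly more than 10% nonzero cells; each
remaining zero is replaced by that gene's median across cells, computed on
the pre-imputation values *including* the zeros (the most literal reading
of a median across cells; an exclude-zeros variant is a flag). The imputed
matrix is quantile normalized, log2(x + 1) transformed, standardized
gene-wise, and the per-cell signature score is the mean of the signature
genes in that cell. Per-type summaries report 5/25/50/75/95% quantiles with
linear (type-7) interpolation.

## The synthetic study

The generator produces every input the pipeline consumes, with planted
ground truth, so that each stage can be checked against known structure.
Gene roles partition the universe: cancer-intrinsic metastasis genes
(higher in every metastasis, essential), biopsy-site confounders (higher
only via the metastasis site's tissue, never essential), breast markers
(lower in metastasis, high in normal breast), cell-cycle genes (essential
but not differential) and neutral genes.

Default study conditions (one set of conditions, fixed):

| quantity | default | rationale |
| --- | --- | --- |
| genes / pairs | 5,000 / 60 | desk-scale cohort preserving the paired design's power regime |
| baseline log2 mean | N(5, 2), clipped at 3 | TPM-scale dynamic range; the clip keeps every profile positive so log2 ↔ TPM round-trips exactly |
| intrinsic effect | 1.0 log2 | a consistent 2-fold cancer-intrinsic shift |
| site effect | 3.0 log2 (liver 6.0) | tissue-specific genes are strongly expressed in their tissue; one dominant-effect site emulates liver's outsized contribution |
| sites | liver 34%, lymph node 33%, bone 33% | roughly balanced so every site's confounders are recoverable from 60 pairs |
| role fractions | intrinsic 5%, confounder 4%, breast 5%, cell cycle 5% | planted shifts stay a small share of the transcriptome so quantile normalization is only mildly perturbed |
| noise SD | 0.5 log2 | per-sample biological + technical scatter |
| cell lines | 46, essential fraction 0.8, contamination 0.01 | essential genes depend in most lines; non-essential scores clipped above −0.45 |
| survival | n = 1,000, β = 0.5 per SD of planted score, 30% censoring | hazard exp(β·u) with u ~ N(0,1) loading on intrinsic genes; exponential censoring calibrated by root-finding to the target fraction |
| subtypes | 4, 300 marker genes, effect SD 1.0 | centroids planted on neutral genes, centered across subtypes |
| single cell | 4 types × 150 cells, NB shape 2, 1.5 log2 overexpression | cancer-epithelial cells over-express intrinsic genes; macrophages the dominant site's confounders |

All randomness flows from one master seed through named substreams, so any
single artifact regenerates identically on its own. Metastasis profiles are
built as primary + planted shifts + fresh noise on the log2 scale and
back-transformed as 2^x − 1 (clipped at 0), the exact inverse of the
pipeline's log2(x + 1). External compendium studies share the master truth
but add study-specific noise levels and global platform offsets, which the
pair-centering must remove. The normal-tissue panel gives confounder genes
a shared +1 log2 elevation in every non-breast tissue plus +4 in their own
site's tissue; breast markers get +4 in breast.

What the generator does **not** emulate: count-level sampling noise in
bulk data, gene–gene correlation beyond the planted factors, batch
structure within a study, real PAM50 centroid geometry, cell-type
proportions of real biopsies, or fitted parameters of the real cohorts.
Passing recovery tests therefore demonstrates the machinery is correct
under its assumed model, not that the effect sizes of any real cohort are
attainable.

## Numerical notes and limitations

- **Quantile normalization under the null.** QN maps every sample onto a
  fixed reference multiset, so a gene near the tail of the expression
  distribution takes few discrete values across samples; paired
  differences become sparse and spiky and the per-gene t-test's type I
  error is inflated at the tails (~1.6% at a nominal 0.1% on a null
  cohort). This is a property of quantile normalization followed by
  t-tests, not of the implementation; the type-I calibration of the paired
  test itself is verified without QN, where the empirical null fraction
  matches α to within binomial error. In the planted-effect cohorts, QN's
  compression also produces spurious "lower in metastasis" calls among
  neutral genes — a compositional artifact any real analysis of this
  design inherits.
- The Cox score-test screen is a null-approximation: for genes with very
  large effects its p can differ from the Wald p by an order of magnitude,
  which is immaterial for thresholding at α = 0.01 but should not be used
  to rank extreme hits precisely.
- Problem sizes in the test and acceptance suites (e.g. 20 null cohorts
  for calibration, 50 seeds for p-uniformity, 100 random signatures,
  reduced gene counts in unit fixtures) were chosen as the smallest sizes
  at which the corresponding statistical property is stable; they are the
  package's own defaults for a desk-scale verification run.
- Degenerate inputs are rejected with named errors rather than silently
  repaired: single-sample normalization, zero-SD studies, empty score
  groups, signatures that lose all but one gene to filtering, subtypes
  with fewer than two reference samples.
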