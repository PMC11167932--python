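# metsig

Essential gene signatures of breast cancer metastasis.

When a metastasis is profiled alongside its patient-matched primary tumor,
most of the apparent expression differences come from the tissue at the
biopsy site (liver, lymph node, bone), not from the cancer cells. `metsig`
implements a pipeline that separates the two: it intersects paired
metastasis-vs-primary differential expression with CRISPR gene-dependency
screens in cancer cell lines, on the premise that a transcriptional change
intrinsic to proliferating cancer cells should involve genes those cells
depend on, while genes contributed by contaminating normal tissue should
not.

The package is aimed at computational cancer biologists who want to derive
and characterize such a signature from their own cohorts — or to study the
method's behavior on fully synthetic cohorts with planted ground truth,
which the package generates itself (no external data needed).

## The method

1. **Paired differential expression.** TPM matrices are quantile
   normalized and log2 transformed; per gene, a paired t-test on the
   per-patient differences d_i = met_i − pri_i tests H0: E[d] = 0. Genes
   with p < α (default 0.001) split into metastasis-high and -low sets. The
   aggregate false-discovery rate is estimated as N·α / n_significant.
2. **Essentiality partition.** From a genes × cell-lines effect-score
   matrix (Chronos-style; strongly negative = the line depends on the
   gene), a gene is *essential* when its score is < −0.75 in strictly more
   than 10% of assayed lines. Metastasis-high genes partition into
   essential / intermediate / nonessential (zero lines below threshold);
   the essential ∩ metastasis-high genes are the **essential metastasis
   signature**, and the overlap is quantified with the expected chance
   overlap |A||B|/N, a df-1 chi-square (no continuity correction) and a
   one-sided Fisher test.
3. **Confound diagnostics.** Welch contrast of normal breast vs pooled
   non-breast tissue, cross-tabulations of the metastasis sets against the
   breast sets, immune-marker paired fold changes, and per-biopsy-site
   fold-change summaries (the nonessential set tracks the site; the
   essential set does not).
4. **Replication and scoring.** External paired studies are pair-centered
   and scaled by the per-study SD (unitless differential values), then
   pooled for a replication t-test. A per-sample signature **t-score** is
   the two-sample t-statistic comparing standardized (SD-from-median)
   expression of signature genes vs all other genes; scores enter
   univariate/multivariate Cox models and log-rank tests on score
   tertiles, with a 100-random-signature null for specificity.
5. **Subtyping, regulators, single cells.** Nearest-centroid molecular
   subtype assignment (Pearson correlation to mean-centroid-centered
   subtype averages); TF-target assignment by binding sites within the
   2 kb strand-aware upstream window; knockdown targets below −0.5
   SD-units; hypergeometric enrichment and multiway intersections; and a
   single-cell scoring recipe (filter >10% nonzero, impute zeros with the
   gene median, quantile normalize, log2, standardize, average the
   signature genes per cell).

## Worked example

```python
from metsig import (
    SimConfig, generate_paired_cohort, quantile_normalize, log2_transform,
    paired_differential, select_differential, estimate_fdr,
    count_essential_lines, classify_genes, overlap_stats, PairedCohort,
)
from metsig.simulate import generate_effect_scores

config = SimConfig(seed=1)                     # 5,000 genes, 60 pairs
cohort, truth = generate_paired_cohort(config)
prepped = log2_transform(quantile_normalize(cohort.expr))
cohort = PairedCohort(prepped, cohort.annotation, cohort.pairing)

de = paired_differential(cohort)
higher = select_differential(de, 0.001, "higher")
print(len(higher), round(estimate_fdr(len(de), 0.001, len(higher)), 4))
# 510 0.0098

scores = generate_effect_scores(truth, config)
counts = count_essential_lines(scores)
part = classify_genes(higher, counts)
essential_all = set(
    counts.index[counts["n_lines_essential"] / counts["n_lines_assayed"] > 0.10]
)
res = overlap_stats(higher, essential_all, set(de.index))
print(len(part.essential), len(part.nonessential), round(res.expected, 1))
# 252 149 51.0
```

510 of 5,000 genes are metastasis-high at p < 0.001 (estimated aggregate
FDR ~1%); 252 of them are also CRISPR-essential — five times the 51
expected by chance (chi-square p < 1e−100) — and those 252 recover the
planted cancer-intrinsic genes, while the 149 nonessential genes are
dominated by biopsy-site markers.

The same analysis runs end to end from the shell:

```bash
metsig run-all --seed 1 --outdir out/
```

which writes every stage's tables plus `out/manifest.json` (seed, config,
headline statistics, output checksums).

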