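"""Tissue-confound diagnostics.

The nonessential metastasis genes largely reflect the non-cancer tissue at
the biopsy site rather than cancer-intrinsic change. This module provides the
evidence machinery: a normal breast vs non-breast tissue contrast, 2×2
cross-tabulations of metastasis gene sets against normal-tissue gene sets,
immune-infiltrate scoring on paired fold changes, and per-site fold-change
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ContingencyResult, ExpressionMatrix, LOG2, MetsigError, PairedCohort
from .essentiality import overlap_stats

QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass
class TissueContrastResult:
    """Per-gene Welch t contrast of one tissue vs the pooled rest."""

    table: pd.DataFrame  # columns t, p
    alpha: float

    @property
    def high_in_target(self) -> set:
        mask = (self.table["p"] < self.alpha) & (self.table["t"] > 0)
        return set(self.table.index[mask])

    @property
    def low_in_target(self) -> set:
        mask = (self.table["p"] < self.alpha) & (self.table["t"] < 0)
        return set(self.table.index[mask])


def tissue_contrast(
    panel: ExpressionMatrix,
    tissue_labels: pd.Series,
    target_label: str,
    alpha: float,
) -> TissueContrastResult:
    """Welch two-sample t-test per gene: target tissue vs pooled others.

    ``tissue_labels`` maps sample → tissue; all non-target tissues are pooled
    into one comparison group.
    """
    panel.require_units(LOG2)
    labels = tissue_labels.reindex(panel.samples)
    in_target = (labels == target_label).to_numpy()
    if in_target.sum() < 2 or (~in_target).sum() < 2:
        raise MetsigError("both tissue groups need at least 2 samples")
    values = panel.values.to_numpy(dtype=float)
    t, p = stats.ttest_ind(values[:, in_target], values[:, ~in_target], axis=1, equal_var=False)
    table = pd.DataFrame({"t": t, "p": p}, index=panel.genes)
    return TissueContrastResult(table=table, alpha=alpha)


def crosstab_sets(
    met_high: set,
    met_low: set,
    breast_high: set,
    breast_low: set,
    universe: set,
) -> dict[str, ContingencyResult]:
    """All four metastasis-set × breast-set overlap analyses.

    The headline pattern: metastasis-high genes are enriched among genes LOW
    in normal breast (they mark the non-breast biopsy-site tissue), and
    vice versa.
    """
    return {
        "met_high_x_breast_low": overlap_stats(met_high, breast_low, universe),
        "met_high_x_breast_high": overlap_stats(met_high, breast_high, universe),
        "met_low_x_breast_high": overlap_stats(met_low, breast_high, universe),
        "met_low_x_breast_low": overlap_stats(met_low, breast_low, universe),
    }


def immune_infiltrate_score(
    cohort: PairedCohort,
    marker_sets: dict[str, set],
) -> pd.DataFrame:
    """Summary of immune-marker paired fold changes across patients.

    Returns one row per marker set with columns ``mean``, ``t``, ``p``
    (one-sample t-test of the per-patient mean fold changes against 0).
    Use :func:`immune_patient_scores` for the per-patient matrix itself.
    """
    scores = immune_patient_scores(cohort, marker_sets)
    rows = {}
    for name in scores.columns:
        vals = scores[name].to_numpy()
        if np.all(vals == vals[0]):
            t, p = (0.0, 1.0) if vals[0] == 0 else (np.sign(vals[0]) * np.inf, np.nextafter(0, 1))
        else:
            t, p = stats.ttest_1samp(vals, 0.0)
        rows[name] = {"mean": vals.mean(), "t": float(t), "p": float(p)}
    return pd.DataFrame(rows).T


def immune_patient_scores(cohort: PairedCohort, marker_sets: dict[str, set]) -> pd.DataFrame:
    """Per-patient mean paired log2 fold change for each marker set."""
    cohort.expr.require_units(LOG2)
    diffs = cohort.paired_differences()
    out = {}
    for name, genes in marker_sets.items():
        present = [g for g in diffs.index if g in genes]
        if not present:
            raise MetsigError(f"marker set {name!r} has no genes in the cohort")
        out[name] = diffs.loc[present].mean(axis=0)
    return pd.DataFrame(out)


def site_foldchange_summary(
    cohort: PairedCohort,
    gene_set: set,
    quantiles: tuple = QUANTILES,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-metastasis mean paired fold change over a gene set, summarized by site.

    Returns ``(per_sample, per_site)``: the per-metastasis-sample means
    (indexed by patient, with the site as a second level) and per-site
    quantiles (5/25/50/75/95% by default, linear interpolation).
    """
    diffs = cohort.paired_differences()
    present = [g for g in diffs.index if g in gene_set]
    if not present:
        raise MetsigError("gene set has no genes in the cohort")
    per_patient = diffs.loc[present].mean(axis=0)
    sites = cohort.metastasis_sites()
    per_sample = pd.DataFrame({"mean_fold_change": per_patient, "site": sites})
    per_site = (
        per_sample.groupby("site")["mean_fold_change"]
        .quantile(list(quantiles))
        .unstack()
    )
    per_site.columns = [f"q{int(q * 100)}" for q in quantiles]
    return per_sample, per_site


def site_dispersion_ratio(
    cohort: PairedCohort,
    nonessential: set,
    essential: set,
) -> float:
    """Across-site variance of median fold change: nonessential over essential.

    A large ratio quantifies the claim that nonessential-gene fold changes
    track the biopsy site while essential-gene fold changes are homogeneous
    across sites.
    """
    _, ness = site_foldchange_summary(cohort, nonessential)
    _, ess = site_foldchange_summary(cohort, essential)
    var_ness = float(ness["q50"].var(ddof=1))
    var_ess = float(ess["q50"].var(ddof=1))
    if var_ess == 0:
        return np.inf
    return var_ness / var_ess
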