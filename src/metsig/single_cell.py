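"""Single-cell signature scoring.

Scoring recipe for a genes × cells counts matrix: keep genes with >10%
nonzero values, replace each zero with the gene's median across cells,
quantile normalize, log2 transform, standardize gene-wise to SD from the
median, and average the signature genes within each cell profile. Scores are
then summarized per cell type.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MetsigError, TPM
from .prep import log2_transform, quantile_normalize, standardize_sd_from_median

SUMMARY_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


def filter_genes(counts: pd.DataFrame, min_nonzero_frac: float = 0.10) -> pd.DataFrame:
    """Keep genes whose fraction of nonzero cells is strictly above the cutoff."""
    frac = (counts.to_numpy() != 0).mean(axis=1)
    return counts.loc[frac > min_nonzero_frac]


def impute_zeros(counts: pd.DataFrame, include_zeros: bool = True) -> pd.DataFrame:
    """Replace each zero entry by the gene's median across cells.

    Medians are computed on the pre-imputation values; by default zeros are
    included in the median (``include_zeros=False`` computes the median of
    the nonzero values instead). Nonzero entries are untouched.
    """
    values = counts.to_numpy(dtype=float)
    if include_zeros:
        med = np.median(values, axis=1)
    else:
        masked = np.where(values != 0, values, np.nan)
        with np.errstate(all="ignore"):
            med = np.nanmedian(masked, axis=1)
        med = np.nan_to_num(med, nan=0.0)
    out = np.where(values == 0, med[:, None], values)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def score_cells(
    counts: pd.DataFrame,
    signature: set,
    min_nonzero_frac: float = 0.10,
    include_zeros_in_median: bool = True,
) -> pd.Series:
    """Per-cell mean standardized expression of the signature genes.

    Runs the full recipe (filter → impute → quantile normalize → log2 →
    SD-from-median) and averages the surviving signature genes within each
    cell. Fails if fewer than 2 signature genes survive, naming the missing
    genes.
    """
    kept = filter_genes(counts, min_nonzero_frac)
    surviving = [g for g in kept.index if g in signature]
    if len(surviving) < 2:
        lost = sorted(set(signature) - set(surviving))
        raise MetsigError(
            f"only {len(surviving)} signature genes survive filtering; lost e.g. {lost[:10]}"
        )
    imputed = impute_zeros(kept, include_zeros=include_zeros_in_median)
    m = ExpressionMatrix(imputed, TPM)
    m = quantile_normalize(m)
    m = log2_transform(m, offset=1.0)
    m = standardize_sd_from_median(m)
    present = [g for g in surviving if g in m.genes]
    if len(present) < 2:
        raise MetsigError("signature genes lost to zero-variance standardization")
    return m.values.loc[present].mean(axis=0).rename("score")


def summarize_by_type(scores: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Per-cell-type score quantiles (5/25/50/75/95%, linear interpolation)."""
    labels = labels.reindex(scores.index)
    if labels.isna().any():
        raise MetsigError("cell-type labels must cover all scored cells")
    out = scores.groupby(labels).quantile(list(SUMMARY_QUANTILES)).unstack()
    out.columns = [f"q{int(q * 100)}" for q in SUMMARY_QUANTILES]
    out["n_cells"] = labels.value_counts().reindex(out.index)
    return out
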