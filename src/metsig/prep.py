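"""Normalization primitives: quantile normalization, log2, SD-from-median.

These three operations are the shared preprocessing vocabulary of every stage:
bulk cohorts are quantile normalized and log2 transformed before paired
testing; profiles are standardized gene-wise to standard deviations from the
median before signature scoring.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import LOG2, SD_UNITS, TPM, ExpressionMatrix, MetsigError

log = logging.getLogger(__name__)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the common empirical distribution.

    The reference distribution is the vector of row means of the
    column-sorted matrix. Each column's values are replaced by the reference
    values at their ranks; tied values within a column receive the mean of
    the reference values their rank range spans. Gene order is preserved.
    """
    if m.units not in (TPM, LOG2):
        raise MetsigError(f"quantile normalization expects tpm or log2 units, got {m.units}")
    if m.n_samples < 2:
        raise MetsigError("quantile normalization needs at least 2 samples")

    values = m.values.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranked = reference.copy()
        # average the reference over each group of tied column values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(col)]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                ranked[s:e] = reference[s:e].mean()
        out[order, j] = ranked
    return m.copy_with(pd.DataFrame(out, index=m.genes, columns=m.samples))


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(x + offset); TPM in, log2 units out."""
    m.require_units(TPM)
    if offset < 0:
        raise MetsigError("offset must be non-negative")
    if (m.values.to_numpy() < 0).any():
        raise MetsigError("negative values in TPM matrix")
    return m.copy_with(np.log2(m.values + offset), units=LOG2)


def back_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Inverse of :func:`log2_transform`: 2**x − offset, clipped at 0."""
    m.require_units(LOG2)
    values = (np.exp2(m.values) - offset).clip(lower=0.0)
    return m.copy_with(values, units=TPM)


def standardize_sd_from_median(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene on its median and scale to unit standard deviation.

    Genes with zero SD across samples carry no information for correlation or
    scoring; they are dropped (with a logged count). SD uses the n−1
    denominator.
    """
    m.require_units(LOG2)
    if m.n_samples < 2:
        raise MetsigError("standardization needs at least 2 samples")
    med = m.values.median(axis=1)
    sd = m.values.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("standardize_sd_from_median: dropped %d zero-variance genes", n_dropped)
    centered = m.values.loc[keep].sub(med[keep], axis=0).div(sd[keep], axis=0)
    return m.copy_with(centered, units=SD_UNITS)
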