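"""Nearest-centroid molecular subtyping.

A reference cohort with known subtype labels yields per-gene subtype mean
profiles, centered on the mean centroid (the unweighted mean of the subtype
means). Unlabeled profiles are standardized within each (study, role) block
and assigned the subtype whose centered centroid they correlate with best
(Pearson, over the genes common to model and profiles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, LOG2, MetsigError, SD_UNITS
from .prep import standardize_sd_from_median

log = logging.getLogger(__name__)


@dataclass
class CentroidModel:
    """Per-gene, per-subtype means centered on the mean centroid."""

    centroids: pd.DataFrame  # genes x subtypes, row means are 0

    @property
    def subtypes(self) -> list[str]:
        return list(self.centroids.columns)

    @property
    def genes(self) -> pd.Index:
        return self.centroids.index


def build_centroids(reference: ExpressionMatrix, labels: pd.Series) -> CentroidModel:
    """Fit a centered centroid model from labeled reference profiles."""
    labels = labels.reindex(reference.samples)
    if labels.isna().any():
        raise MetsigError("labels must cover every reference sample")
    counts = labels.value_counts()
    if (counts < 2).any():
        small = sorted(counts.index[counts < 2])
        raise MetsigError(f"subtypes with <2 reference samples: {small}")
    means = reference.values.T.groupby(labels).mean().T  # genes x subtypes
    means = means[sorted(means.columns)]
    mean_centroid = means.mean(axis=1)
    return CentroidModel(centroids=means.sub(mean_centroid, axis=0))


def assign_subtype(
    profiles: ExpressionMatrix,
    model: CentroidModel,
    blocks: pd.Series | None = None,
) -> pd.DataFrame:
    """Assign each profile the subtype of its best-correlated centroid.

    ``blocks`` maps sample → normalization block (e.g. "study1/metastasis");
    profiles are standardized to SD-from-median within each block before
    correlating. Ties are broken by the model's fixed subtype order, with a
    warning. Returns per-sample ``subtype`` plus one correlation column per
    subtype.
    """
    if blocks is None:
        blocks = pd.Series("all", index=profiles.samples)
    blocks = blocks.reindex(profiles.samples)

    pieces = []
    for _, cols in profiles.values.T.groupby(blocks):
        block_expr = ExpressionMatrix(cols.T, profiles.units)
        if block_expr.units == LOG2:
            block_expr = standardize_sd_from_median(block_expr)
        block_expr.require_units(SD_UNITS)
        pieces.append(_correlate_block(block_expr, model))
    out = pd.concat(pieces).reindex(profiles.samples)
    return out


def _correlate_block(block: ExpressionMatrix, model: CentroidModel) -> pd.DataFrame:
    common = block.genes.intersection(model.genes)
    if len(common) < 3:
        raise MetsigError("fewer than 3 genes common to profiles and centroid model")
    x = block.values.loc[common].to_numpy(dtype=float)  # genes x samples
    c = model.centroids.loc[common].to_numpy(dtype=float)  # genes x subtypes

    xc = x - x.mean(axis=0, keepdims=True)
    cc = c - c.mean(axis=0, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=0))[:, None] * np.sqrt((cc**2).sum(axis=0))[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc.T @ cc) / denom  # samples x subtypes

    best = corr.argmax(axis=1)
    ties = (corr == corr.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        log.warning("assign_subtype: %d samples with tied correlations; fixed subtype order used", int(ties.sum()))
    labels = [model.subtypes[i] for i in best]
    out = pd.DataFrame(corr, index=block.samples, columns=[f"r_{s}" for s in model.subtypes])
    out.insert(0, "subtype", labels)
    return out


def assign_with_annotation(
    profiles: ExpressionMatrix,
    model: CentroidModel,
    annotated: pd.Series | None = None,
    blocks: pd.Series | None = None,
) -> pd.DataFrame:
    """Inferred labels, overridden by original study annotation where present."""
    out = assign_subtype(profiles, model, blocks=blocks)
    out["source"] = "inferred"
    if annotated is not None:
        known = annotated.reindex(profiles.samples).dropna()
        out.loc[known.index, "subtype"] = known
        out.loc[known.index, "source"] = "annotation"
    return out
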