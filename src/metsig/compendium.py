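"""Cross-study compendium normalization and replication testing.

External paired metastasis/primary studies are made comparable by centering
each metastasis profile on its paired primary (primaries become zero) and
dividing, within each study, by the standard deviation across all centered
entries — rendering differential expression unitless. A signature replicates
when its genes are again differential (pooled paired t-test across studies)
in the external compendium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ContingencyResult,
    LOG2,
    MetsigError,
    PairedCohort,
    ROLE_METASTASIS,
)
from .essentiality import overlap_stats


@dataclass
class CompendiumStudy:
    """One study after pair-centering and per-study SD scaling.

    ``centered`` holds the unitless (metastasis − primary) / study-SD values,
    one column per pair (patient). ``scale`` is the SD that was divided out.
    """

    study_id: str
    centered: pd.DataFrame
    scale: float


def center_and_scale(study: PairedCohort, study_id: str = "study", per_profile_sd: bool = False) -> CompendiumStudy:
    """Center metastases on their primaries and scale by the study SD.

    The SD is computed jointly across all centered metastasis and primary
    entries (the primaries contribute zeros); with ``per_profile_sd`` each
    centered metastasis profile is instead divided by its own SD.
    """
    study.expr.require_units(LOG2)
    diffs = study.paired_differences()
    # centered matrix over all samples: metastasis columns hold diffs, primaries 0
    stacked = np.concatenate([diffs.to_numpy().ravel(), np.zeros(diffs.size)])
    if per_profile_sd:
        sds = diffs.std(axis=0, ddof=1)
        if (sds == 0).any():
            raise MetsigError(f"degenerate study {study_id!r}: a centered profile has zero SD")
        scaled = diffs.div(sds, axis=1)
        scale = float(sds.mean())
    else:
        scale = float(np.std(stacked, ddof=1))
        if scale == 0:
            raise MetsigError(f"degenerate study {study_id!r}: zero SD across centered profiles")
        scaled = diffs / scale
    return CompendiumStudy(study_id=study_id, centered=scaled, scale=scale)


def pooled_paired_test(studies: list[CompendiumStudy]) -> pd.DataFrame:
    """Pooled paired t-test per gene across all studies' pairs.

    Pairs from all studies are concatenated on the genes common to every
    study; per gene, a one-sample t-test of the unitless centered values
    against zero. Returns columns ``mean_diff``, ``t``, ``p``, ``n_pairs``.
    """
    if not studies:
        raise MetsigError("empty compendium")
    common = studies[0].centered.index
    for s in studies[1:]:
        common = common.intersection(s.centered.index)
    if len(common) == 0:
        raise MetsigError("no genes common to all studies")
    pooled = np.concatenate([s.centered.loc[common].to_numpy() for s in studies], axis=1)
    n = pooled.shape[1]
    mean = pooled.mean(axis=1)
    sd = pooled.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(sd == 0, np.where(mean == 0, 1.0, np.nextafter(0, 1)), p)
    t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return pd.DataFrame({"mean_diff": mean, "t": t, "p": p, "n_pairs": n}, index=common)


@dataclass
class ReplicationResult:
    per_gene: pd.DataFrame  # pooled test restricted to the signature
    replicated: set
    replicated_fraction: float
    enrichment: ContingencyResult
    n_signature_in_compendium: int


def replication_test(
    studies: list[CompendiumStudy],
    signature: set,
    alpha: float = 0.05,
) -> ReplicationResult:
    """Which signature genes are again metastasis-high in the compendium?

    A gene replicates when its pooled paired p is strictly below ``alpha``
    with a positive mean. The enrichment of the signature among all
    compendium-replicated genes is tested one-sided Fisher over the
    compendium gene universe.
    """
    pooled = pooled_paired_test(studies)
    universe = set(pooled.index)
    present = universe & set(signature)
    if not present:
        raise MetsigError("signature has no genes in the compendium")
    replicated_all = set(pooled.index[(pooled["p"] < alpha) & (pooled["mean_diff"] > 0)])
    replicated = present & replicated_all
    enrichment = overlap_stats(present, replicated_all, universe)
    return ReplicationResult(
        per_gene=pooled.loc[sorted(present)],
        replicated=replicated,
        replicated_fraction=len(replicated) / len(present),
        enrichment=enrichment,
        n_signature_in_compendium=len(present),
    )


def published_signature_overlap(
    published: set,
    essential: set,
    nonessential: set,
    universe: set,
) -> dict[str, ContingencyResult]:
    """Fisher overlap of a previously published signature with both classes."""
    return {
        "published_x_essential": overlap_stats(published, essential, universe),
        "published_x_nonessential": overlap_stats(published, nonessential, universe),
    }
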