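"""CRISPR essentiality integration.

Gene effect scores (Chronos-style; strongly negative means the cell line
depends on the gene) are thresholded per line, metastasis-high genes are
partitioned into essential / intermediate / nonessential classes, and the
overlap of gene sets is quantified with a 2×2 contingency analysis
(expected chance overlap, Pearson chi-square without continuity correction,
one-sided Fisher via the hypergeometric tail).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ContingencyResult, MetsigError

log = logging.getLogger(__name__)

ESSENTIAL = "essential"
INTERMEDIATE = "intermediate"
NONESSENTIAL = "nonessential"

DEFAULT_THRESHOLD = -0.75
DEFAULT_MIN_FRACTION = 0.10


def count_essential_lines(scores: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Per gene: number of lines strictly below ``threshold`` and number assayed.

    ``scores`` is genes × cell lines; missing entries are excluded from both
    the numerator and the denominator.
    """
    if not np.isfinite(threshold):
        raise MetsigError("threshold must be finite")
    values = scores.to_numpy(dtype=float)
    assayed = np.isfinite(values)
    below = assayed & (values < threshold)
    return pd.DataFrame(
        {
            "n_lines_essential": below.sum(axis=1),
            "n_lines_assayed": assayed.sum(axis=1),
        },
        index=scores.index,
    )


@dataclass
class EssentialityPartition:
    """Essential / intermediate / nonessential classes of metastasis-high genes."""

    table: pd.DataFrame  # columns n_lines_essential, n_lines_assayed, fraction_essential, class
    threshold: float
    min_fraction: float

    def genes_in_class(self, cls: str) -> set:
        return set(self.table.index[self.table["class"] == cls])

    @property
    def essential(self) -> set:
        return self.genes_in_class(ESSENTIAL)

    @property
    def nonessential(self) -> set:
        return self.genes_in_class(NONESSENTIAL)

    @property
    def intermediate(self) -> set:
        return self.genes_in_class(INTERMEDIATE)


def classify_genes(
    higher_set: set,
    counts: pd.DataFrame,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    threshold: float = DEFAULT_THRESHOLD,
) -> EssentialityPartition:
    """Partition metastasis-high genes by their essential-line fraction.

    essential: fraction strictly > ``min_fraction`` of assayed lines;
    nonessential: zero essential lines; intermediate: the remainder. Genes
    with zero assayed lines are excluded (logged).
    """
    genes = [g for g in counts.index if g in higher_set]
    missing = higher_set - set(genes)
    if missing:
        log.info("classify_genes: %d metastasis-high genes lack effect scores", len(missing))
    sub = counts.loc[genes]
    assayed = sub["n_lines_assayed"].to_numpy()
    keep = assayed > 0
    if (~keep).any():
        log.info("classify_genes: excluded %d genes with zero assayed lines", int((~keep).sum()))
    sub = sub.loc[keep]
    frac = sub["n_lines_essential"] / sub["n_lines_assayed"]
    cls = np.where(
        frac > min_fraction,
        ESSENTIAL,
        np.where(sub["n_lines_essential"] == 0, NONESSENTIAL, INTERMEDIATE),
    )
    table = sub.assign(fraction_essential=frac, **{"class": cls})
    return EssentialityPartition(table=table, threshold=threshold, min_fraction=min_fraction)


def overlap_stats(set_a: set, set_b: set, universe: set) -> ContingencyResult:
    """2×2 overlap analysis of two gene sets over a universe.

    Expected overlap |A||B|/N; Pearson chi-square (df 1, no continuity
    correction) with its two-sided p; one-sided Fisher enrichment p via the
    hypergeometric upper tail; odds ratio ad/bc (infinite with a zero b or c
    cell, flagged).
    """
    if not universe:
        raise MetsigError("empty universe")
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise MetsigError("sets must be subsets of the universe")
    n = len(universe)
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = n - a - b - c
    expected = len(set_a) * len(set_b) / n

    table = np.array([[a, b], [c, d]], dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    exp_cells = np.outer(row, col) / n
    if (exp_cells == 0).any():
        chi2 = 0.0
        chi2_p = 1.0
    else:
        chi2 = float(((table - exp_cells) ** 2 / exp_cells).sum())
        chi2_p = float(stats.chi2.sf(chi2, df=1))

    fisher_p = float(stats.hypergeom.sf(a - 1, n, len(set_a), len(set_b)))

    zero_cell = b == 0 or c == 0
    if zero_cell:
        odds = np.inf if a * d > 0 else (0.0 if a == 0 and d == 0 else np.inf)
    else:
        odds = (a * d) / (b * c)

    return ContingencyResult(
        a=a, b=b, c=c, d=d,
        expected=expected,
        chi2=chi2, chi2_p=chi2_p,
        fisher_p=fisher_p,
        odds_ratio=float(odds),
        zero_cell=bool(zero_cell),
    )
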