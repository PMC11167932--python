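"""Gene-set enrichment machinery.

Serves four uses: curated collections (GO/wikiPathway-style GMT sets),
transcription-factor target sets built from binding intervals falling in the
promoter-proximal upstream window of a gene, siRNA-knockdown target sets
(genes under-expressed upon knockdown), and the multiway intersection of the
resulting gene sets. Enrichment uses the one-sided Fisher (hypergeometric
upper-tail) test over an explicit gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MetsigError

DEFAULT_UPSTREAM_WINDOW = 2000
DEFAULT_KNOCKDOWN_THRESHOLD = -0.5


def upstream_window(start: int, end: int, strand: str, window: int = DEFAULT_UPSTREAM_WINDOW) -> tuple[int, int]:
    """The [lo, hi) interval immediately 5' of a gene (0-based, half-open).

    + strand: [start − window, start); − strand: [end, end + window); clipped
    at 0.
    """
    if strand == "+":
        return max(0, start - window), start
    if strand == "-":
        return end, end + window
    raise MetsigError(f"strand must be '+' or '-', got {strand!r}")


def map_tf_targets(
    sites: pd.DataFrame,
    loci: pd.DataFrame,
    window: int = DEFAULT_UPSTREAM_WINDOW,
    strand_aware: bool = True,
) -> dict[str, set]:
    """TF → target-gene sets by upstream-window interval intersection.

    ``sites``: columns ``chrom``, ``start``, ``end``, ``name`` (the TF);
    ``loci``: columns ``chrom``, ``start``, ``end``, ``name`` (the gene),
    ``strand``. A gene is a target of a TF iff any of the TF's sites overlaps
    the gene's upstream window (nonempty intersection of half-open
    intervals). With ``strand_aware=False`` every window is [start−window,
    start). Malformed records (end ≤ start) are rejected per record.
    """
    loci = loci[loci["end"] > loci["start"]]
    sites = sites[sites["end"] > sites["start"]]

    windows = []
    for row in loci.itertuples(index=False):
        strand = row.strand if strand_aware else "+"
        lo, hi = upstream_window(int(row.start), int(row.end), strand, window)
        windows.append((row.chrom, lo, hi, row.name))
    win = pd.DataFrame(windows, columns=["chrom", "lo", "hi", "gene"])

    targets: dict[str, set] = {tf: set() for tf in sites["name"].unique()}
    for chrom, wchrom in win.groupby("chrom"):
        schrom = sites[sites["chrom"] == chrom]
        if schrom.empty:
            continue
        lo = wchrom["lo"].to_numpy()[:, None]
        hi = wchrom["hi"].to_numpy()[:, None]
        s_start = schrom["start"].to_numpy()[None, :]
        s_end = schrom["end"].to_numpy()[None, :]
        overlap = (s_start < hi) & (s_end > lo)  # nonempty half-open intersection
        gene_idx, site_idx = np.nonzero(overlap)
        genes = wchrom["gene"].to_numpy()
        tfs = schrom["name"].to_numpy()
        for g, s in zip(gene_idx, site_idx):
            targets[tfs[s]].add(genes[g])
    return targets


def knockdown_targets(
    km: pd.DataFrame,
    threshold: float = DEFAULT_KNOCKDOWN_THRESHOLD,
) -> dict[str, set]:
    """Per knockdown profile, the genes strictly below ``threshold``.

    ``km`` is genes × knockdown profiles in SD-from-median units; the
    under-expressed genes are the downstream targets of the knocked-down
    gene.
    """
    values = km.to_numpy(dtype=float)
    out = {}
    for j, kd in enumerate(km.columns):
        out[kd] = set(km.index[values[:, j] < threshold])
    return out


@dataclass
class EnrichmentReport:
    """Per-set one-sided Fisher enrichment of a query gene set."""

    table: pd.DataFrame  # per set: overlap, set_size, query_size, universe_size, expected, fisher_p
    universe_size: int

    def significant(self, alpha: float) -> list[str]:
        return list(self.table.index[self.table["fisher_p"] < alpha])


def fisher_enrichment(
    query: set,
    collection: dict[str, set],
    universe: set,
) -> EnrichmentReport:
    """Hypergeometric upper-tail enrichment of ``query`` in each named set.

    Sets are restricted to the universe before testing; the p-value is
    P(overlap ≥ observed) under random draws of the query from the universe.
    """
    if not universe:
        raise MetsigError("empty universe")
    universe = set(universe)
    query = set(query) & universe
    n = len(universe)
    k = len(query)
    rows = {}
    for name, genes in collection.items():
        genes_in = set(genes) & universe
        m = len(genes_in)
        a = len(query & genes_in)
        p = float(stats.hypergeom.sf(a - 1, n, m, k))
        rows[name] = {
            "overlap": a,
            "set_size": m,
            "query_size": k,
            "universe_size": n,
            "expected": m * k / n,
            "fisher_p": p,
        }
    table = pd.DataFrame(rows).T
    for col in ("overlap", "set_size", "query_size", "universe_size"):
        table[col] = table[col].astype(int)
    return EnrichmentReport(table=table, universe_size=n)


def multiway_intersection(sets: dict[str, set]) -> dict[tuple[str, ...], set]:
    """Exact membership regions of 2–4 named gene sets.

    Returns every nonempty-key region of the Venn partition: the key is the
    sorted tuple of set names a gene belongs to, and regions partition the
    union (each gene appears in exactly one region). All 2^k − 1 regions are
    present as keys, possibly with empty gene sets.
    """
    names = sorted(sets)
    if not 2 <= len(names) <= 4:
        raise MetsigError("multiway intersection expects 2-4 sets")
    regions: dict[tuple[str, ...], set] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[combo] = set()
    for gene in set().union(*sets.values()):
        member = tuple(n for n in names if gene in sets[n])
        regions[member].add(gene)
    return regions
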