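"""Synthetic cohorts with planted ground truth.

Every input the pipeline consumes can be generated here with the statistical
structure the analysis assumes: paired tumors whose metastasis profiles carry
cancer-intrinsic effects plus biopsy-site tissue confounding, CRISPR effect
scores in which the intrinsic (and cell-cycle) genes are essential, a normal
tissue panel, a survival cohort whose hazard follows a planted signature
score, TF-binding and knockdown target structure, and cell-type-structured
single-cell counts. The planted roles and parameters are recorded in a
:class:`~metsig.containers.TruthTable` so every downstream stage can be
checked against its ground truth.

Gene roles
----------
``intrinsic_met``
    higher in metastasis in every patient (cancer-cell intrinsic) and
    essential in most cell lines — the planted analogue of the essential
    metastasis signature.
``site_confounder``
    higher in metastasis only when the metastasis was biopsied from that
    gene's site (normal-tissue contamination); never essential.
``breast_marker``
    lower in metastasis (the breast tissue left behind), high in normal
    breast.
``cell_cycle``
    essential but not metastasis-differential.
``neutral``
    everything else.

All randomness flows from a single master seed through named substreams, so
each output is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import (
    ExpressionMatrix,
    LOG2,
    MetsigError,
    PairedCohort,
    TPM,
    TruthTable,
)

ROLES = ("intrinsic_met", "site_confounder", "breast_marker", "cell_cycle", "neutral")

# substream ids: one fixed integer per generated artifact
_STREAMS = {
    "roles": 1,
    "baseline": 2,
    "cohort": 3,
    "effect_scores": 4,
    "tissue_panel": 5,
    "survival": 6,
    "regulators": 7,
    "single_cell": 8,
    "subtypes": 9,
    "compendium": 10,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study. Effects and noise are log2 units."""

    n_genes: int = 5000
    n_patients: int = 60
    site_fractions: dict = field(
        default_factory=lambda: {"liver": 0.34, "lymph_node": 0.33, "bone": 0.33}
    )
    dominant_site: str = "liver"

    # gene-role fractions (remainder is neutral)
    role_fractions: dict = field(
        default_factory=lambda: {
            "intrinsic_met": 0.05,
            "site_confounder": 0.04,
            "breast_marker": 0.05,
            "cell_cycle": 0.05,
        }
    )

    # planted effect sizes (log2)
    intrinsic_effect: float = 1.0
    site_effect: float = 3.0
    dominant_site_multiplier: float = 2.0
    breast_effect: float = 1.0
    noise_sd: float = 0.5

    # CRISPR effect scores
    n_cell_lines: int = 46
    essential_fraction: float = 0.8
    essential_noise_fraction: float = 0.01

    # normal-tissue panel
    n_tissue_samples: int = 30
    panel_effect: float = 4.0
    panel_shared_effect: float = 1.0

    # survival cohort
    n_survival_samples: int = 1000
    survival_beta: float = 0.5
    censoring_fraction: float = 0.3
    baseline_hazard: float = 1.0 / 60.0  # events per month
    survival_loading: float = 1.0

    # subtypes
    subtypes: tuple = ("basal", "her2", "luminal_a", "luminal_b")
    n_subtype_genes: int = 300
    subtype_effect: float = 1.0

    # regulators
    n_tfs: int = 5
    n_tf_targets: int = 150
    tf_intrinsic_bias: float = 0.6
    n_decoy_sites: int = 40
    n_knockdowns: int = 10
    n_knockdown_targets: int = 100
    site_length: int = 50
    gene_spacing: int = 10_000
    gene_length: int = 1_000

    # single cell
    cell_types: tuple = ("epithelial", "macrophage", "t_cell", "fibroblast")
    cancer_cell_type: str = "epithelial"
    confounded_cell_type: str = "macrophage"
    n_cells_per_type: int = 150
    sc_overexpression: float = 1.5  # log2 fold bump of planted genes
    sc_dispersion: float = 2.0  # negative-binomial shape

    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_patients", "n_cell_lines", "n_survival_samples", "n_cells_per_type"):
            if getattr(self, name) <= 0:
                raise MetsigError(f"{name} must be positive")
        if not np.isclose(sum(self.site_fractions.values()), 1.0):
            raise MetsigError("site fractions must sum to 1")
        if sum(self.role_fractions.values()) > 1.0 + 1e-9:
            raise MetsigError("role fractions must sum to <= 1")
        if self.dominant_site not in self.site_fractions:
            raise MetsigError("dominant site must be one of the sites")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise MetsigError("censoring fraction must be in [0, 1)")


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream]])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def make_truth(config: SimConfig) -> TruthTable:
    """Assign gene roles, site maps, subtype centroids and planted effects."""
    genes = _gene_ids(config.n_genes)
    rng = _rng(config, "roles")
    shuffled = list(rng.permutation(genes))
    roles = pd.Series("neutral", index=pd.Index(genes, name="gene"), name="role")
    pos = 0
    assigned = {}
    for role in ("intrinsic_met", "site_confounder", "breast_marker", "cell_cycle"):
        k = int(round(config.role_fractions.get(role, 0.0) * config.n_genes))
        assigned[role] = shuffled[pos : pos + k]
        roles.loc[assigned[role]] = role
        pos += k

    sites = sorted(config.site_fractions)
    site_genes = {s: [] for s in sites}
    for i, g in enumerate(assigned["site_confounder"]):
        site_genes[sites[i % len(sites)]].append(g)

    # subtype centroids planted on neutral genes so they stay orthogonal to roles
    rng_sub = _rng(config, "subtypes")
    neutral = [g for g in shuffled[pos:]]
    marker_genes = list(rng_sub.choice(neutral, size=min(config.n_subtype_genes, len(neutral)), replace=False))
    deltas = rng_sub.normal(0.0, config.subtype_effect, size=(len(marker_genes), len(config.subtypes)))
    deltas -= deltas.mean(axis=1, keepdims=True)
    centroids = pd.DataFrame(deltas, index=pd.Index(marker_genes, name="gene"), columns=list(config.subtypes))

    effects = {
        "intrinsic_effect": config.intrinsic_effect,
        "site_effect": config.site_effect,
        "dominant_site_effect": config.site_effect * config.dominant_site_multiplier,
        "breast_effect": config.breast_effect,
        "noise_sd": config.noise_sd,
        "subtype_effect": config.subtype_effect,
    }
    return TruthTable(
        roles=roles,
        effects=effects,
        site_genes=site_genes,
        subtype_centroids=centroids,
        survival_beta=config.survival_beta,
        seed=config.seed,
    )


def _baseline_means(config: SimConfig) -> pd.Series:
    """Per-gene baseline log2 expression: N(5, 2) clipped below at 3.

    The lower clip keeps every profile strictly positive on the TPM scale
    even after the largest planted down-shift plus noise, so the log2 ↔ TPM
    round trip is exact.
    """
    rng = _rng(config, "baseline")
    mu = rng.normal(5.0, 2.0, size=config.n_genes)
    return pd.Series(np.clip(mu, 3.0, None), index=pd.Index(_gene_ids(config.n_genes), name="gene"))


def _site_effect(config: SimConfig, site: str) -> float:
    eff = config.site_effect
    if site == config.dominant_site:
        eff *= config.dominant_site_multiplier
    return eff


def _simulate_pairs(
    truth: TruthTable,
    config: SimConfig,
    rng: np.random.Generator,
    n_patients: int,
    noise_sd: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """log2 (metastasis, primary) profiles plus per-patient site/subtype draws."""
    mu = _baseline_means(config)
    genes = list(mu.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_g = config.n_genes

    sites = sorted(config.site_fractions)
    probs = np.array([config.site_fractions[s] for s in sites])
    patient_sites = rng.choice(sites, size=n_patients, p=probs)
    patient_subtypes = rng.choice(list(config.subtypes), size=n_patients)

    delta_met = np.zeros((n_g, n_patients))
    intrinsic_idx = [gene_pos[g] for g in truth.genes_with_role("intrinsic_met")]
    breast_idx = [gene_pos[g] for g in truth.genes_with_role("breast_marker")]
    delta_met[intrinsic_idx, :] += config.intrinsic_effect
    delta_met[breast_idx, :] -= config.breast_effect
    for j, site in enumerate(patient_sites):
        idx = [gene_pos[g] for g in truth.site_genes[site]]
        delta_met[idx, j] += _site_effect(config, site)

    sub_delta = np.zeros((n_g, n_patients))
    marker_idx = [gene_pos[g] for g in truth.subtype_centroids.index]
    for j, st in enumerate(patient_subtypes):
        sub_delta[marker_idx, j] = truth.subtype_centroids[st].to_numpy()

    base = mu.to_numpy()[:, None] + sub_delta
    primary = base + rng.normal(0.0, noise_sd, size=(n_g, n_patients)) if noise_sd > 0 else base
    met = primary + delta_met
    if noise_sd > 0:
        met = met + rng.normal(0.0, noise_sd, size=(n_g, n_patients))
    return met, primary, patient_sites, patient_subtypes


def _assemble_cohort(
    truth: TruthTable,
    met: np.ndarray,
    primary: np.ndarray,
    patient_sites: np.ndarray,
    patient_subtypes: np.ndarray,
    study: str,
    prefix: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stack paired log2 profiles into (values, annotation, pairing) frames."""
    n_p = met.shape[1]
    patients = [f"{prefix}P{j:03d}" for j in range(n_p)]
    met_samples = [f"{p}_met" for p in patients]
    pri_samples = [f"{p}_pri" for p in patients]
    values = pd.DataFrame(
        np.concatenate([met, primary], axis=1),
        index=truth.roles.index,
        columns=met_samples + pri_samples,
    )
    annotation = pd.DataFrame(
        {
            "patient": patients + patients,
            "role": ["metastasis"] * n_p + ["primary"] * n_p,
            "site": list(patient_sites) + ["breast"] * n_p,
            "study": study,
            "subtype": list(patient_subtypes) * 2,
        },
        index=pd.Index(met_samples + pri_samples, name="sample"),
    )
    pairing = pd.DataFrame(
        {"metastasis": met_samples, "primary": pri_samples},
        index=pd.Index(patients, name="patient"),
    )
    return values, annotation, pairing


def generate_paired_cohort(config: SimConfig) -> tuple[PairedCohort, TruthTable]:
    """Paired metastasis/primary cohort in TPM units, plus its truth table.

    Each primary is the gene baseline plus a subtype shift and noise; the
    paired metastasis adds the intrinsic effect on ``intrinsic_met`` genes,
    the biopsy-site effect on that site's confounder genes (the dominant
    site gets a doubled effect), subtracts the breast-marker effect, and adds
    fresh noise. Values are back-transformed to TPM as 2^x − 1.
    """
    truth = make_truth(config)
    rng = _rng(config, "cohort")
    met, primary, patient_sites, patient_subtypes = _simulate_pairs(
        truth, config, rng, config.n_patients, config.noise_sd
    )
    values, annotation, pairing = _assemble_cohort(
        truth, met, primary, patient_sites, patient_subtypes, study="synthetic"
    )
    tpm = (np.exp2(values) - 1.0).clip(lower=0.0)
    cohort = PairedCohort(ExpressionMatrix(tpm, TPM), annotation, pairing)
    return cohort, truth


def generate_effect_scores(truth: TruthTable, config: SimConfig) -> pd.DataFrame:
    """Chronos-style gene effect scores, genes × cell lines.

    ``intrinsic_met`` and ``cell_cycle`` genes score below −0.75 in a
    Bernoulli(``essential_fraction``) draw of lines; every other gene's
    scores stay at or above −0.5 except for a Bernoulli
    (``essential_noise_fraction``) contamination of essential-like draws.
    """
    rng = _rng(config, "effect_scores")
    genes = list(truth.roles.index)
    n_g, n_l = len(genes), config.n_cell_lines
    essential_gene = truth.roles.isin(["intrinsic_met", "cell_cycle"]).to_numpy()
    p_ess = np.where(essential_gene, config.essential_fraction, config.essential_noise_fraction)
    is_essential = rng.random((n_g, n_l)) < p_ess[:, None]

    nonessential_scores = np.clip(rng.normal(0.0, 0.2, size=(n_g, n_l)), -0.45, None)
    essential_scores = -0.75 - np.abs(rng.normal(0.5, 0.2, size=(n_g, n_l)))
    scores = np.where(is_essential, essential_scores, nonessential_scores)
    lines = [f"CL{j:02d}" for j in range(n_l)]
    return pd.DataFrame(scores, index=pd.Index(genes, name="gene"), columns=lines)


def generate_normal_tissue_panel(truth: TruthTable, config: SimConfig) -> tuple[ExpressionMatrix, pd.Series]:
    """Normal-tissue panel (log2 units) with tissue labels.

    Tissues are breast plus one tissue per metastatic site. Breast-marker
    genes are elevated in breast by ``panel_effect`` log2 units. Confounder
    genes mark non-breast tissue: elevated by ``panel_shared_effect`` in
    every non-breast tissue and by ``panel_effect`` in their own site's
    tissue.
    """
    rng = _rng(config, "tissue_panel")
    mu = _baseline_means(config)
    genes = list(mu.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    tissues = ["breast"] + sorted(truth.site_genes)
    n_t = config.n_tissue_samples
    confounder_idx = [gene_pos[g] for s in truth.site_genes.values() for g in s]

    cols, labels = [], []
    blocks = []
    for tissue in tissues:
        shift = np.zeros(config.n_genes)
        if tissue == "breast":
            idx = [gene_pos[g] for g in truth.genes_with_role("breast_marker")]
            shift[idx] = config.panel_effect
        else:
            shift[confounder_idx] = config.panel_shared_effect
            idx = [gene_pos[g] for g in truth.site_genes[tissue]]
            shift[idx] = config.panel_effect
        block = np.tile(mu.to_numpy()[:, None] + shift[:, None], (1, n_t))
        if config.noise_sd > 0:
            block = block + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_t))
        blocks.append(block)
        cols.extend(f"{tissue}_{j:02d}" for j in range(n_t))
        labels.extend([tissue] * n_t)

    values = pd.DataFrame(
        np.concatenate(blocks, axis=1), index=pd.Index(genes, name="gene"), columns=cols
    )
    return ExpressionMatrix(values, LOG2), pd.Series(labels, index=values.columns, name="tissue")


def _censoring_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate giving the target expected censored fraction."""
    def frac(rate: float) -> float:
        return float(np.mean(rate / (rate + hazards))) - target

    return brentq(frac, 1e-12, 1e9)


def generate_survival_cohort(truth: TruthTable, config: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Primary-tumor expression (log2) and a survival table with planted hazard.

    Each sample carries a latent signature activity u ~ N(0,1) that loads on
    the ``intrinsic_met`` genes; event times are exponential with hazard
    ``baseline_hazard · exp(β·u)`` and censoring is independent exponential
    calibrated to the configured censoring fraction. The planted score u is
    recorded in the table as ``planted_score``.
    """
    rng = _rng(config, "survival")
    mu = _baseline_means(config)
    genes = list(mu.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = config.n_survival_samples

    u = rng.normal(0.0, 1.0, size=n)
    loading = np.zeros(config.n_genes)
    loading[[gene_pos[g] for g in truth.genes_with_role("intrinsic_met")]] = config.survival_loading
    values = mu.to_numpy()[:, None] + loading[:, None] * u[None, :]
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))

    samples = [f"S{j:04d}" for j in range(n)]
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples), LOG2
    )

    hazards = config.baseline_hazard * np.exp(config.survival_beta * u)
    event_times = rng.exponential(1.0 / hazards)
    if config.censoring_fraction > 0:
        rate_c = _censoring_rate(hazards, config.censoring_fraction)
        censor_times = rng.exponential(1.0 / rate_c, size=n)
    else:
        censor_times = np.full(n, np.inf)
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)

    survival = pd.DataFrame(
        {"time": time, "event": event, "planted_score": u},
        index=pd.Index(samples, name="sample"),
    )
    return expr, survival


def generate_regulator_data(
    truth: TruthTable, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene loci (BED-like), TF binding sites, and a knockdown matrix.

    Planted TF targets get a binding interval inside the strand-aware 2 kb
    upstream window of the gene; decoy sites land well outside every window.
    Planted knockdown targets get values strictly below −0.5 in the matching
    knockdown column; all other entries are clipped at −0.45. The planted
    maps are recorded on the truth table.
    """
    rng = _rng(config, "regulators")
    genes = list(truth.roles.index)
    n_g = len(genes)
    intrinsic = truth.genes_with_role("intrinsic_met")

    starts = config.gene_spacing * (1 + np.arange(n_g))
    strands = rng.choice(["+", "-"], size=n_g)
    loci = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + config.gene_length,
            "name": genes,
            "score": 0,
            "strand": strands,
        }
    )
    locus_by_gene = loci.set_index("name")

    window = 2000
    tf_names = [f"TF{i + 1}" for i in range(config.n_tfs)]
    tf_targets: dict[str, set] = {}
    site_rows = []
    n_targets = min(config.n_tf_targets, n_g)
    for i, tf in enumerate(tf_names):
        if i < (config.n_tfs + 1) // 2:
            n_int = min(int(round(config.tf_intrinsic_bias * n_targets)), len(intrinsic))
            chosen = list(rng.choice(intrinsic, size=n_int, replace=False))
            others = [g for g in genes if g not in set(chosen)]
            chosen += list(rng.choice(others, size=n_targets - n_int, replace=False))
        else:
            chosen = list(rng.choice(genes, size=n_targets, replace=False))
        tf_targets[tf] = set(chosen)
        for g in chosen:
            row = locus_by_gene.loc[g]
            if row["strand"] == "+":
                lo, hi = row["start"] - window, row["start"]
            else:
                lo, hi = row["end"], row["end"] + window
            offset = int(rng.integers(0, window - config.site_length))
            site_rows.append(("chr1", lo + offset, lo + offset + config.site_length, tf))
        # decoys: placed past the gene body, outside every upstream window
        decoy_genes = rng.choice(genes, size=config.n_decoy_sites)
        for g in decoy_genes:
            s = int(locus_by_gene.loc[g, "start"]) + 5000
            site_rows.append(("chr1", s, s + config.site_length, tf))
    sites = pd.DataFrame(site_rows, columns=["chrom", "start", "end", "name"])

    kd_pool = intrinsic + truth.genes_with_role("neutral")
    kd_genes = list(rng.choice(kd_pool, size=config.n_knockdowns, replace=False))
    kd_targets: dict[str, set] = {}
    km = np.clip(rng.normal(0.0, 0.15, size=(n_g, config.n_knockdowns)), -0.45, None)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_kd_targets = min(config.n_knockdown_targets, n_g)
    for j, kd in enumerate(kd_genes):
        n_int = min(n_kd_targets // 2, len(intrinsic))
        chosen = list(rng.choice(intrinsic, size=n_int, replace=False))
        others = [g for g in genes if g not in set(chosen)]
        chosen += list(rng.choice(others, size=n_kd_targets - n_int, replace=False))
        kd_targets[kd] = set(chosen)
        idx = [gene_pos[g] for g in chosen]
        km[idx, j] = -0.5 - np.abs(rng.normal(0.5, 0.2, size=len(idx)))
    knockdown = pd.DataFrame(
        km, index=pd.Index(genes, name="gene"), columns=[f"KD_{g}" for g in kd_genes]
    )

    truth.tf_targets = tf_targets
    truth.knockdown_targets = {f"KD_{g}": t for g, t in kd_targets.items()}
    return loci, sites, knockdown


def generate_single_cell(truth: TruthTable, config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial counts (genes × cells) with cell-type labels.

    Cancer-epithelial cells overexpress the ``intrinsic_met`` genes; the
    configured non-cancer cell type overexpresses the dominant site's
    confounder genes; counts are Gamma-Poisson with shape
    ``sc_dispersion``.
    """
    rng = _rng(config, "single_cell")
    genes = list(truth.roles.index)
    n_g = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=n_g)

    cols, labels, blocks = [], [], []
    bump = 2.0**config.sc_overexpression
    for ct in config.cell_types:
        mean = base_mean.copy()
        if ct == config.cancer_cell_type:
            idx = [gene_pos[g] for g in truth.genes_with_role("intrinsic_met")]
            mean[idx] *= bump
        elif ct == config.confounded_cell_type:
            idx = [gene_pos[g] for g in truth.site_genes[config.dominant_site]]
            mean[idx] *= bump
        shape = config.sc_dispersion
        lam = mean[:, None] * rng.gamma(shape, 1.0 / shape, size=(n_g, config.n_cells_per_type))
        blocks.append(rng.poisson(lam))
        cols.extend(f"{ct}_{j:03d}" for j in range(config.n_cells_per_type))
        labels.extend([ct] * config.n_cells_per_type)

    counts = pd.DataFrame(
        np.concatenate(blocks, axis=1), index=pd.Index(genes, name="gene"), columns=cols
    )
    return counts, pd.Series(labels, index=counts.columns, name="cell_type")


def generate_compendium(
    truth: TruthTable,
    config: SimConfig,
    n_studies: int = 3,
    pairs_per_study: int = 20,
) -> list[PairedCohort]:
    """Small external paired studies sharing the cohort's truth structure.

    Each study shares the master truth (same planted roles and effects) but
    has its own noise level and a study-specific global offset, emulating
    platform differences that the compendium normalization must remove.
    Returned in log2 units.
    """
    cohorts = []
    for k in range(n_studies):
        rng = np.random.default_rng([config.seed, _STREAMS["compendium"], k])
        met, primary, patient_sites, patient_subtypes = _simulate_pairs(
            truth, config, rng, pairs_per_study, config.noise_sd * (1.0 + 0.5 * k)
        )
        offset = 2.0 * k  # study-specific platform shift, removed by centering
        values, annotation, pairing = _assemble_cohort(
            truth, met + offset, primary + offset, patient_sites, patient_subtypes,
            study=f"study_{k}", prefix=f"st{k}_",
        )
        cohorts.append(PairedCohort(ExpressionMatrix(values, LOG2), annotation, pairing))
    return cohorts
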