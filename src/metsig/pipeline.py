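"""End-to-end orchestration.

Runs the full analysis — preprocessing, paired differential expression,
essentiality partition, confound diagnostics, compendium replication,
signature scoring with survival association, subtype assignment, regulator
enrichment, and single-cell scoring — on a synthetic cohort (default) or on
user-supplied inputs, writing every stage output plus a machine-readable
manifest (inputs, seed, per-stage headline statistics, output checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .compendium import center_and_scale, replication_test
from .confound import (
    crosstab_sets,
    immune_infiltrate_score,
    site_dispersion_ratio,
    site_foldchange_summary,
    tissue_contrast,
)
from .containers import ExpressionMatrix, MetsigError, PairedCohort, SD_UNITS
from .enrichment import fisher_enrichment, knockdown_targets, map_tf_targets, multiway_intersection
from .essentiality import classify_genes, count_essential_lines, overlap_stats
from .paired_de import HIGHER, LOWER, estimate_fdr, paired_differential, select_differential
from .prep import log2_transform, quantile_normalize, standardize_sd_from_median
from .simulate import (
    SimConfig,
    generate_compendium,
    generate_effect_scores,
    generate_normal_tissue_panel,
    generate_regulator_data,
    generate_single_cell,
    generate_survival_cohort,
    generate_paired_cohort,
)
from .single_cell import score_cells, summarize_by_type
from .subtype import assign_subtype, build_centroids
from .survival import (
    cox_multivariate,
    cox_univariate,
    logrank_groups,
    prognosis_gene_overlap,
    random_signature_null,
    score_cohort,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds of the analysis, with their default values.

    Defaults mirror the analysis constants: differential expression at
    p<0.001 (relaxed 0.01 for intersection exercises), essentiality below
    −0.75 in >10% of lines, normal-tissue contrast at p<1e−6, replication at
    p<0.05, knockdown targets below −0.5, a 2 kb upstream window, 100 random
    signatures, tertile score groups.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str = "metsig_run"
    de_alpha: float = 0.001
    relaxed_de_alpha: float = 0.01
    essential_threshold: float = -0.75
    min_essential_fraction: float = 0.10
    tissue_alpha: float = 1e-6
    replication_alpha: float = 0.05
    knockdown_threshold: float = -0.5
    upstream_window: int = 2000
    n_random_signatures: int = 100
    logrank_cutpoints: tuple = (1 / 3, 2 / 3)
    enrichment_alpha: float = 0.01
    # optional user-supplied inputs (TSV paths); when unset, synthetic data are generated
    expression_path: str | None = None
    annotation_path: str | None = None
    pairing_path: str | None = None
    effect_scores_path: str | None = None

    @property
    def seed(self) -> int:
        return self.sim.seed

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        sim = SimConfig(**raw.pop("sim", {}))
        if "logrank_cutpoints" in raw:
            raw["logrank_cutpoints"] = tuple(raw["logrank_cutpoints"])
        return cls(sim=sim, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_record = dataclasses.asdict(config)
    config_record.pop("outdir")  # not part of the analysis identity
    manifest: dict = {
        "seed": config.seed,
        "config": _jsonable(config_record),
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    def save(name: str, writer, *args) -> None:
        path = outdir / name
        writer(*args, path)
        written.append(path)

    stage = "simulate"
    try:
        synthetic = config.expression_path is None
        if synthetic:
            cohort, truth = generate_paired_cohort(config.sim)
            scores = generate_effect_scores(truth, config.sim)
            save("expression_tpm.tsv", msio.write_expression_tsv, cohort.expr)
            save("annotation.tsv", msio.write_annotation_tsv, cohort.annotation)
            save("pairing.tsv", msio.write_pairing_tsv, cohort.pairing)
            save("truth.tsv", msio.write_truth_tsv, truth.roles)
            save("effect_scores.tsv", lambda df, p: df.to_csv(p, sep="\t"), scores)
            manifest["stages"][stage] = {
                "n_genes": config.sim.n_genes,
                "n_pairs": config.sim.n_patients,
                "roles": _jsonable(truth.roles.value_counts().to_dict()),
            }
        else:
            truth = None
            raw = msio.read_paired_cohort(
                config.expression_path, config.annotation_path, config.pairing_path, units="tpm"
            )
            cohort = raw
            if config.effect_scores_path is None:
                raise MetsigError("user-supplied runs need --effect-scores")
            scores = pd.read_csv(config.effect_scores_path, sep="\t", index_col=0)
            manifest["stages"][stage] = {"n_genes": cohort.expr.n_genes, "n_pairs": cohort.n_pairs}

        stage = "prep"
        prepped = log2_transform(quantile_normalize(cohort.expr))
        cohort = PairedCohort(prepped, cohort.annotation, cohort.pairing)
        save("expression_log2.tsv", msio.write_expression_tsv, prepped)
        manifest["stages"][stage] = {"units": prepped.units, "n_genes": prepped.n_genes}

        stage = "paired_de"
        de = paired_differential(cohort)
        higher = select_differential(de, config.de_alpha, HIGHER)
        lower = select_differential(de, config.de_alpha, LOWER)
        higher_relaxed = select_differential(de, config.relaxed_de_alpha, HIGHER)
        fdr = estimate_fdr(len(de), config.de_alpha, len(higher) + len(lower))
        save("paired_de.tsv", lambda df, p: df.to_csv(p, sep="\t"), de)
        save("metastasis_sets.gmt", msio.write_gmt, {"met_higher": higher, "met_lower": lower})
        manifest["stages"][stage] = {
            "n_genes": len(de),
            "n_higher": len(higher),
            "n_lower": len(lower),
            "fdr_estimate": fdr,
        }

        stage = "essentiality"
        counts = count_essential_lines(scores, config.essential_threshold)
        frac = counts["n_lines_essential"] / counts["n_lines_assayed"].clip(lower=1)
        essential_all = set(counts.index[frac > config.min_essential_fraction])
        universe = set(de.index) & set(counts.index)
        overlap = overlap_stats(higher & universe, essential_all & universe, universe)
        lower_overlap = overlap_stats(lower & universe, essential_all & universe, universe)
        partition = classify_genes(higher, counts, config.min_essential_fraction, config.essential_threshold)
        essential_sig = partition.essential
        nonessential_sig = partition.nonessential
        save("essentiality_partition.tsv", lambda df, p: df.to_csv(p, sep="\t"), partition.table)
        save(
            "signatures.gmt",
            msio.write_gmt,
            {"essential_metastasis": essential_sig, "nonessential_metastasis": nonessential_sig},
        )
        manifest["stages"][stage] = {
            "n_essential_universe": len(essential_all),
            "higher_x_essential": _jsonable(overlap.as_dict()),
            "lower_x_essential_fisher_p": lower_overlap.fisher_p,
            "n_essential_signature": len(essential_sig),
            "n_nonessential_signature": len(nonessential_sig),
            "n_intermediate": len(partition.intermediate),
        }

        if synthetic:
            stage = "confound"
            panel, tissue_labels = generate_normal_tissue_panel(truth, config.sim)
            contrast = tissue_contrast(panel, tissue_labels, "breast", config.tissue_alpha)
            tabs = crosstab_sets(
                higher, lower, contrast.high_in_target, contrast.low_in_target,
                set(de.index) & set(contrast.table.index),
            )
            marker_sets = {"breast_resident_markers": set(truth.genes_with_role("breast_marker")[:50])}
            immune = immune_infiltrate_score(cohort, marker_sets)
            _, ess_by_site = site_foldchange_summary(cohort, essential_sig)
            _, ness_by_site = site_foldchange_summary(cohort, nonessential_sig)
            dispersion = site_dispersion_ratio(cohort, nonessential_sig, essential_sig)
            save("tissue_contrast.tsv", lambda df, p: df.to_csv(p, sep="\t"), contrast.table)
            save("site_summary_essential.tsv", lambda df, p: df.to_csv(p, sep="\t"), ess_by_site)
            save("site_summary_nonessential.tsv", lambda df, p: df.to_csv(p, sep="\t"), ness_by_site)
            manifest["stages"][stage] = {
                "crosstab": {k: _jsonable(v.as_dict()) for k, v in tabs.items()},
                "marker_means": _jsonable(immune["mean"].to_dict()),
                "site_dispersion_ratio": dispersion,
            }

            stage = "compendium"
            studies = [
                center_and_scale(c, study_id=f"study_{k}")
                for k, c in enumerate(generate_compendium(truth, config.sim))
            ]
            replication = replication_test(studies, essential_sig, config.replication_alpha)
            save("replication.tsv", lambda df, p: df.to_csv(p, sep="\t"), replication.per_gene)
            manifest["stages"][stage] = {
                "n_signature_in_compendium": replication.n_signature_in_compendium,
                "replicated_fraction": replication.replicated_fraction,
                "replication_fisher_p": replication.enrichment.fisher_p,
            }

            stage = "signature_survival"
            surv_expr, surv_table = generate_survival_cohort(truth, config.sim)
            std_expr = standardize_sd_from_median(surv_expr)
            sig_scores = score_cohort(std_expr, essential_sig)
            cox = cox_univariate(sig_scores, surv_table[["time", "event"]])
            planted_cox = cox_univariate(
                surv_table["planted_score"].rename("score"), surv_table[["time", "event"]]
            )
            groups, logrank_p = logrank_groups(
                sig_scores, surv_table[["time", "event"]], config.logrank_cutpoints
            )
            proliferation = std_expr.values.loc[
                [g for g in truth.genes_with_role("cell_cycle") if g in std_expr.genes][:20]
            ].mean(axis=0)
            multi = cox_multivariate(
                sig_scores, proliferation.to_frame("proliferation"), surv_table[["time", "event"]]
            )
            null = random_signature_null(
                std_expr, essential_sig, surv_table[["time", "event"]],
                n=config.n_random_signatures, seed=config.seed,
            )
            _, prognosis = prognosis_gene_overlap(
                std_expr, surv_table[["time", "event"]], config.enrichment_alpha, essential_sig
            )
            save("survival.csv", msio.write_survival_csv, surv_table)
            save("signature_scores.tsv", lambda s, p: s.to_csv(p, sep="\t"), sig_scores)
            save("random_signature_null.tsv", lambda df, p: df.to_csv(p, sep="\t"), null.null_table)
            manifest["stages"][stage] = {
                "cox_coef": cox.coef,
                "cox_p": cox.p,
                "planted_cox_coef": planted_cox.coef,
                "planted_beta": truth.survival_beta,
                "logrank_p": logrank_p,
                "group_sizes": _jsonable(groups.value_counts().to_dict()),
                "multivariate_signature_p": multi.loc["score", "p"],
                "null_sd_rank": null.sd_rank,
                "null_cox_p_rank": null.cox_p_rank,
                "worse_prognosis_fisher_p": prognosis["worse_x_signature"].fisher_p,
            }

            stage = "subtype"
            primaries = ExpressionMatrix(
                cohort.expr.values[cohort.pairing["primary"]], cohort.expr.units
            )
            primary_labels = cohort.annotation.loc[primaries.samples, "subtype"]
            model = build_centroids(primaries, primary_labels)
            mets = ExpressionMatrix(
                cohort.expr.values[cohort.pairing["metastasis"]], cohort.expr.units
            )
            assigned = assign_subtype(mets, model)
            planted = cohort.annotation.loc[mets.samples, "subtype"]
            accuracy = float((assigned["subtype"] == planted).mean())
            save("subtype_assignments.tsv", lambda df, p: df.to_csv(p, sep="\t"), assigned)
            manifest["stages"][stage] = {"accuracy_vs_planted": accuracy}

            stage = "regulator_enrichment"
            loci, sites, km = generate_regulator_data(truth, config.sim)
            save("gene_loci.bed", msio.write_bed, loci)
            save("tf_sites.bed", msio.write_bed, sites)
            tf_sets = map_tf_targets(sites, loci, window=config.upstream_window)
            kd_sets = knockdown_targets(km, config.knockdown_threshold)
            gene_universe = set(de.index)
            tf_report = fisher_enrichment(essential_sig, tf_sets, gene_universe)
            kd_report = fisher_enrichment(essential_sig, kd_sets, gene_universe)
            enriched_tfs = set().union(
                *(tf_sets[t] for t in tf_report.significant(config.enrichment_alpha))
            ) if tf_report.significant(config.enrichment_alpha) else set()
            enriched_kds = set().union(
                *(kd_sets[t] for t in kd_report.significant(config.enrichment_alpha))
            ) if kd_report.significant(config.enrichment_alpha) else set()
            regions = multiway_intersection(
                {
                    "met_higher_relaxed": higher_relaxed,
                    "essential": essential_all,
                    "tf_enriched_targets": enriched_tfs,
                    "kd_enriched_targets": enriched_kds,
                }
            )
            save("tf_enrichment.tsv", lambda df, p: df.to_csv(p, sep="\t"), tf_report.table)
            save("kd_enrichment.tsv", lambda df, p: df.to_csv(p, sep="\t"), kd_report.table)
            manifest["stages"][stage] = {
                "n_tfs_enriched": len(tf_report.significant(config.enrichment_alpha)),
                "n_kds_enriched": len(kd_report.significant(config.enrichment_alpha)),
                "four_way_core": len(regions[tuple(sorted(regions, key=len)[-1])])
                if regions else 0,
                "region_sizes": {
                    "&".join(k): len(v) for k, v in sorted(regions.items()) if len(k) == 4
                },
            }

            stage = "single_cell"
            sc_counts, sc_labels = generate_single_cell(truth, config.sim)
            ess_scores = score_cells(sc_counts, essential_sig)
            ness_scores = score_cells(sc_counts, nonessential_sig)
            ess_summary = summarize_by_type(ess_scores, sc_labels)
            ness_summary = summarize_by_type(ness_scores, sc_labels)
            save("sc_essential_by_type.tsv", lambda df, p: df.to_csv(p, sep="\t"), ess_summary)
            save("sc_nonessential_by_type.tsv", lambda df, p: df.to_csv(p, sep="\t"), ness_summary)
            manifest["stages"][stage] = {
                "essential_median_by_type": _jsonable(ess_summary["q50"].to_dict()),
                "nonessential_median_by_type": _jsonable(ness_summary["q50"].to_dict()),
            }
    except MetsigError as exc:
        raise MetsigError(f"stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(written)}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True))
    return manifest
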