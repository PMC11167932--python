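import numpy as np
import pandas as pd
import pytest

from metsig.containers import MetsigError
from metsig.simulate import (
    SimConfig,
    generate_compendium,
    generate_effect_scores,
    generate_paired_cohort,
    generate_regulator_data,
    generate_single_cell,
    generate_survival_cohort,
    generate_normal_tissue_panel,
    make_truth,
)


def zero_noise_config(**kwargs) -> SimConfig:
    return SimConfig(n_genes=600, n_patients=12, noise_sd=0.0, seed=5, **kwargs)


class TestDeterminismAndInvariants:
    def test_same_seed_reproduces_byte_identical_cohort(self):
        config = SimConfig(n_genes=400, n_patients=10, seed=3)
        c1, t1 = generate_paired_cohort(config)
        c2, t2 = generate_paired_cohort(config)
        pd.testing.assert_frame_equal(c1.expr.values, c2.expr.values)
        pd.testing.assert_series_equal(t1.roles, t2.roles)
        s1 = generate_effect_scores(t1, config)
        s2 = generate_effect_scores(t2, config)
        pd.testing.assert_frame_equal(s1, s2)

    def test_tpm_nonnegative_and_pairing_consistent(self):
        cohort, _ = generate_paired_cohort(SimConfig(n_genes=400, n_patients=10, seed=3))
        assert (cohort.expr.values.to_numpy() >= 0).all()
        assert cohort.annotation.index.is_unique
        met_roles = cohort.annotation.loc[cohort.pairing["metastasis"], "role"]
        pri_roles = cohort.annotation.loc[cohort.pairing["primary"], "role"]
        assert (met_roles == "metastasis").all()
        assert (pri_roles == "primary").all()

    def test_roles_partition_gene_universe(self):
        truth = make_truth(SimConfig(n_genes=500, seed=2))
        assert set(truth.roles.unique()) <= {
            "intrinsic_met", "site_confounder", "breast_marker", "cell_cycle", "neutral"
        }
        assert len(truth.roles) == 500
        all_site_genes = [g for s in truth.site_genes.values() for g in s]
        assert len(all_site_genes) == len(set(all_site_genes))

    def test_invalid_config_rejected(self):
        with pytest.raises(MetsigError):
            SimConfig(n_genes=0)
        with pytest.raises(MetsigError):
            SimConfig(site_fractions={"liver": 0.5})
        with pytest.raises(MetsigError):
            SimConfig(role_fractions={"intrinsic_met": 0.9, "site_confounder": 0.5})


class TestZeroNoiseLimits:
    def test_all_effects_zero_gives_identical_pairs(self):
        config = zero_noise_config(
            intrinsic_effect=0.0, site_effect=0.0, breast_effect=0.0, subtype_effect=0.0
        )
        cohort, _ = generate_paired_cohort(config)
        diffs = cohort.paired_differences()
        np.testing.assert_allclose(diffs.to_numpy(), 0.0, atol=1e-12)

    def test_intrinsic_genes_have_exact_unit_fold_change(self):
        config = zero_noise_config(intrinsic_effect=1.0)
        cohort, truth = generate_paired_cohort(config)
        log2 = np.log2(cohort.expr.values + 1.0)
        met = log2[cohort.pairing["metastasis"]].to_numpy()
        pri = log2[cohort.pairing["primary"]].to_numpy()
        intrinsic = truth.roles == "intrinsic_met"
        np.testing.assert_allclose((met - pri)[intrinsic.to_numpy()], 1.0, atol=1e-9)


class TestEffectScores:
    def test_zero_noise_fraction_keeps_confounders_clean(self):
        config = zero_noise_config(essential_noise_fraction=0.0)
        truth = make_truth(config)
        scores = generate_effect_scores(truth, config)
        confounders = [g for s in truth.site_genes.values() for g in s]
        assert (scores.loc[confounders].to_numpy() >= -0.75).all()

    def test_essential_line_count_matches_binomial_expectation(self):
        config = SimConfig(n_genes=2000, essential_fraction=0.9, seed=8)
        truth = make_truth(config)
        scores = generate_effect_scores(truth, config)
        intrinsic = truth.genes_with_role("intrinsic_met")
        below = (scores.loc[intrinsic] < -0.75).sum(axis=1)
        # 46 lines at rate 0.9: expectation 41.4, averaged over 100 genes
        assert below.mean() == pytest.approx(0.9 * 46, abs=1.0)


class TestTissuePanel:
    def test_breast_markers_higher_in_breast(self):
        config = zero_noise_config()
        truth = make_truth(config)
        panel, labels = generate_normal_tissue_panel(truth, config)
        breast_cols = labels.index[labels == "breast"]
        other_cols = labels.index[labels != "breast"]
        markers = truth.genes_with_role("breast_marker")
        breast_mean = panel.values.loc[markers, breast_cols].mean(axis=1)
        other_mean = panel.values.loc[markers, other_cols].mean(axis=1)
        assert (breast_mean > other_mean).all()


class TestSurvivalCohort:
    def test_censoring_fraction_matches_config(self):
        config = SimConfig(n_genes=300, n_survival_samples=2000, censoring_fraction=0.3, seed=4)
        truth = make_truth(config)
        _, surv = generate_survival_cohort(truth, config)
        assert 1 - surv["event"].mean() == pytest.approx(0.3, abs=0.05)

    def test_null_beta_gives_near_zero_coefficient(self):
        from metsig.survival import cox_univariate

        config = SimConfig(n_genes=300, n_survival_samples=1000, survival_beta=0.0, seed=6)
        truth = make_truth(config)
        _, surv = generate_survival_cohort(truth, config)
        res = cox_univariate(surv["planted_score"].rename("score"), surv[["time", "event"]])
        assert abs(res.coef) < 0.15

    def test_times_positive_events_binary(self):
        config = SimConfig(n_genes=300, n_survival_samples=500, seed=4)
        truth = make_truth(config)
        _, surv = generate_survival_cohort(truth, config)
        assert (surv["time"] > 0).all()
        assert surv["event"].isin([0, 1]).all()


@pytest.fixture(scope="module")
def regulator():
    config = SimConfig(n_genes=700, seed=19)
    truth = make_truth(config)
    loci, sites, km = generate_regulator_data(truth, config)
    return truth, loci, sites, km


class TestRegulatorData:

    def test_planted_tf_targets_recovered_exactly(self, regulator):
        from metsig.enrichment import map_tf_targets

        truth, loci, sites, _ = regulator
        assert map_tf_targets(sites, loci) == truth.tf_targets

    def test_planted_sites_inside_upstream_windows(self, regulator):
        truth, loci, sites, _ = regulator
        by_gene = loci.set_index("name")
        # every planted target has at least one of its TF's sites in its window
        for tf, targets in truth.tf_targets.items():
            tf_sites = sites[sites["name"] == tf]
            for g in list(targets)[:10]:
                row = by_gene.loc[g]
                if row["strand"] == "+":
                    lo, hi = row["start"] - 2000, row["start"]
                else:
                    lo, hi = row["end"], row["end"] + 2000
                assert ((tf_sites["start"] < hi) & (tf_sites["end"] > lo)).any()

    def test_non_targets_above_knockdown_threshold(self, regulator):
        truth, _, _, km = regulator
        for kd, targets in truth.knockdown_targets.items():
            non_targets = [g for g in km.index if g not in targets]
            assert (km.loc[non_targets, kd] >= -0.5).all()


class TestSingleCellAndCompendium:
    def test_zero_overexpression_equalizes_type_means(self):
        config = SimConfig(n_genes=500, n_cells_per_type=100, sc_overexpression=0.0, seed=23)
        truth = make_truth(config)
        counts, labels = generate_single_cell(truth, config)
        intrinsic = truth.genes_with_role("intrinsic_met")
        means = counts.loc[intrinsic].T.groupby(labels).mean().mean(axis=1)
        assert means.max() - means.min() < 0.25 * means.mean()

    def test_nonzero_fraction_increases_with_planted_mean(self):
        config = SimConfig(n_genes=500, n_cells_per_type=100, seed=23)
        truth = make_truth(config)
        counts, _ = generate_single_cell(truth, config)
        nz = (counts.to_numpy() > 0).mean(axis=1)
        mean_counts = counts.mean(axis=1).to_numpy()
        top = nz[np.argsort(mean_counts)[-100:]].mean()
        bottom = nz[np.argsort(mean_counts)[:100]].mean()
        assert top > bottom

    def test_compendium_studies_share_genes_and_scale(self):
        from metsig.compendium import center_and_scale

        config = SimConfig(n_genes=400, seed=29)
        truth = make_truth(config)
        cohorts = generate_compendium(truth, config, n_studies=2, pairs_per_study=8)
        assert list(cohorts[0].expr.genes) == list(cohorts[1].expr.genes)
        for c in cohorts:
            study = center_and_scale(c)
            stacked = np.concatenate(
                [study.centered.to_numpy().ravel(), np.zeros(study.centered.size)]
            )
            assert np.std(stacked, ddof=1) == pytest.approx(1.0)
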