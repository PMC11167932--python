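import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from metsig.containers import ExpressionMatrix, MetsigError, SD_UNITS
from metsig.prep import standardize_sd_from_median
from metsig.simulate import SimConfig, generate_survival_cohort, make_truth
from metsig.survival import (
    cox_multivariate,
    cox_score_screen,
    cox_univariate,
    logrank_groups,
    prognosis_gene_overlap,
    random_signature_null,
    score_cohort,
    t_score,
)


def sd_profile(values, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return pd.Series(np.asarray(values, float), index=genes)


@pytest.fixture(scope="module")
def survival_data():
    config = SimConfig(n_genes=1000, n_survival_samples=400, seed=9)
    truth = make_truth(config)
    expr, surv = generate_survival_cohort(truth, config)
    return standardize_sd_from_median(expr), surv, truth


class TestTScore:
    def test_hand_welch_example(self):
        # signature {2, 1} vs background {0, -1, 1}: Welch t = 1.9640
        profile = sd_profile([2.0, 1.0, 0.0, -1.0, 1.0])
        score = t_score(profile, {"g0", "g1"})
        assert score == pytest.approx(1.9639610121239317)

    def test_direction_positive_when_signature_high(self):
        profile = sd_profile([1.0, 1.0, 0.0, 0.1, -0.1, 0.0])
        assert t_score(profile, {"g0", "g1"}) > 0

    def test_up_down_signature_antisymmetry(self):
        profile = sd_profile(np.random.default_rng(0).normal(size=10))
        up, down = {"g0", "g1", "g2"}, {"g5", "g6", "g7"}
        assert t_score(profile, up, down) == pytest.approx(-t_score(profile, down, up))

    def test_background_permutation_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=12)
        profile = sd_profile(values)
        sig = {"g0", "g1", "g2"}
        shuffled = profile.copy()
        bg = [g for g in profile.index if g not in sig]
        shuffled.loc[bg] = profile.loc[list(np.random.default_rng(2).permutation(bg))].to_numpy()
        assert t_score(shuffled, sig) == pytest.approx(t_score(profile, sig))

    def test_too_few_signature_genes_rejected(self):
        with pytest.raises(MetsigError):
            t_score(sd_profile([1.0, 2.0, 3.0]), {"g0"})


class TestScoreCohort:
    def test_sample_permutation_permutes_scores(self, survival_data):
        matrix, _, truth = survival_data
        sig = set(truth.genes_with_role("intrinsic_met"))
        scores = score_cohort(matrix, sig)
        perm = list(reversed(matrix.samples))
        permuted = ExpressionMatrix(matrix.values[perm], SD_UNITS)
        np.testing.assert_allclose(score_cohort(permuted, sig).loc[scores.index], scores)

    def test_matches_per_profile_t_score(self, survival_data):
        matrix, _, truth = survival_data
        sig = set(truth.genes_with_role("intrinsic_met"))
        scores = score_cohort(matrix, sig)
        sample = matrix.samples[3]
        assert scores.loc[sample] == pytest.approx(t_score(matrix.values[sample], sig))

    def test_planted_high_samples_score_highest(self, survival_data):
        matrix, surv, truth = survival_data
        sig = set(truth.genes_with_role("intrinsic_met"))
        scores = score_cohort(matrix, sig)
        r = np.corrcoef(scores, surv["planted_score"])[0, 1]
        assert r > 0.95


class TestCox:
    def test_planted_beta_recovered(self, survival_data):
        _, surv, truth = survival_data
        res = cox_univariate(surv["planted_score"].rename("score"), surv[["time", "event"]])
        assert res.coef == pytest.approx(truth.survival_beta, abs=0.2)
        assert res.p < 1e-6

    def test_time_scale_invariance(self, survival_data):
        _, surv, _ = survival_data
        scaled = surv[["time", "event"]].copy()
        scaled["time"] *= 2
        r1 = cox_univariate(surv["planted_score"].rename("score"), surv[["time", "event"]])
        r2 = cox_univariate(surv["planted_score"].rename("score"), scaled)
        assert r1.coef == pytest.approx(r2.coef, rel=1e-6)

    def test_multivariate_with_no_covariates_equals_univariate(self, survival_data):
        _, surv, _ = survival_data
        scores = surv["planted_score"].rename("score")
        uni = cox_univariate(scores, surv[["time", "event"]])
        multi = cox_multivariate(scores, pd.DataFrame(index=surv.index), surv[["time", "event"]])
        assert multi.loc["score", "coef"] == pytest.approx(uni.coef)

    def test_independent_noise_covariate_leaves_signature_effect(self, survival_data):
        _, surv, _ = survival_data
        scores = surv["planted_score"].rename("score")
        rng = np.random.default_rng(3)
        noise = pd.DataFrame({"noise": rng.normal(size=len(surv))}, index=surv.index)
        uni = cox_univariate(scores, surv[["time", "event"]])
        multi = cox_multivariate(scores, noise, surv[["time", "event"]])
        assert multi.loc["score", "coef"] == pytest.approx(uni.coef, abs=0.05)

    def test_no_events_rejected(self):
        surv = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]}, index=["a", "b"])
        with pytest.raises(MetsigError):
            cox_univariate(pd.Series([0.1, 0.2], index=["a", "b"]), surv)


class TestLogrank:
    def test_planted_gradient_detected(self, survival_data):
        matrix, surv, truth = survival_data
        scores = score_cohort(matrix, set(truth.genes_with_role("intrinsic_met")))
        labels, p = logrank_groups(scores, surv[["time", "event"]])
        assert p < 0.01
        assert set(labels.unique()) == {"low", "intermediate", "high"}
        sizes = labels.value_counts()
        assert sizes.max() - sizes.min() <= 2  # tertiles

    def test_null_scores_give_large_p(self, survival_data):
        _, surv, _ = survival_data
        rng = np.random.default_rng(4)
        noise_scores = pd.Series(rng.normal(size=len(surv)), index=surv.index)
        _, p = logrank_groups(noise_scores, surv[["time", "event"]])
        assert p > 0.01


class TestRandomSignatureNull:
    def test_fixed_seed_reproduces_exactly(self, survival_data):
        matrix, surv, truth = survival_data
        sig = set(truth.genes_with_role("intrinsic_met"))
        n1 = random_signature_null(matrix, sig, surv[["time", "event"]], n=5, seed=42)
        n2 = random_signature_null(matrix, sig, surv[["time", "event"]], n=5, seed=42)
        pd.testing.assert_frame_equal(n1.null_table, n2.null_table)

    def test_coordinated_signature_ranks_first(self, survival_data):
        matrix, surv, truth = survival_data
        sig = set(truth.genes_with_role("intrinsic_met"))
        null = random_signature_null(matrix, sig, surv[["time", "event"]], n=10, seed=0)
        assert null.sd_rank == 1
        assert null.cox_p_rank == 1


class TestCoxScreen:
    def test_score_test_agrees_with_lifelines(self, survival_data):
        matrix, surv, _ = survival_data
        screen = cox_score_screen(matrix, surv[["time", "event"]])
        rng = np.random.default_rng(5)
        for gene in rng.choice(matrix.genes, size=5, replace=False):
            df = surv[["time", "event"]].copy()
            df["x"] = matrix.values.loc[gene]
            cph = CoxPHFitter().fit(df, "time", "event")
            wald_p = float(cph.summary.loc["x", "p"])
            coef = float(cph.params_["x"])
            z, p = screen.loc[gene, "z"], screen.loc[gene, "p"]
            assert np.sign(z) == np.sign(coef) or abs(coef) < 0.01
            # score and Wald tests agree closely near the null and to order of magnitude away
            assert np.log10(max(p, 1e-300)) == pytest.approx(np.log10(max(wald_p, 1e-300)), abs=1.0)

    def test_prognosis_overlap_detects_planted_coupling(self, survival_data):
        matrix, surv, truth = survival_data
        sig = set(truth.genes_with_role("intrinsic_met"))
        per_gene, overlaps = prognosis_gene_overlap(matrix, surv[["time", "event"]], 0.01, sig)
        assert overlaps["worse_x_signature"].fisher_p < 1e-6
        assert overlaps["better_x_signature"].a < overlaps["worse_x_signature"].a
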