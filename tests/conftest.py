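import numpy as np
import pandas as pd
import pytest

from metsig.containers import ExpressionMatrix, PairedCohort, LOG2
from metsig.paired_de import paired_differential, select_differential
from metsig.prep import log2_transform, quantile_normalize
from metsig.simulate import SimConfig, generate_paired_cohort


def make_paired_cohort(diffs: np.ndarray, baseline: float = 8.0, genes=None) -> PairedCohort:
    """Cohort with prescribed per-gene, per-patient (met − primary) log2 differences."""
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n_g, n_p = diffs.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(n_g)]
    patients = [f"P{j}" for j in range(n_p)]
    met_cols = [f"{p}_met" for p in patients]
    pri_cols = [f"{p}_pri" for p in patients]
    primary = np.full((n_g, n_p), baseline)
    values = pd.DataFrame(
        np.concatenate([primary + diffs, primary], axis=1),
        index=genes,
        columns=met_cols + pri_cols,
    )
    annotation = pd.DataFrame(
        {
            "patient": patients * 2,
            "role": ["metastasis"] * n_p + ["primary"] * n_p,
            "site": ["liver"] * n_p + ["breast"] * n_p,
        },
        index=met_cols + pri_cols,
    )
    pairing = pd.DataFrame({"metastasis": met_cols, "primary": pri_cols}, index=patients)
    return PairedCohort(ExpressionMatrix(values, LOG2), annotation, pairing)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Reduced synthetic study for unit tests (fast but structurally complete)."""
    # gene count reduced for speed; pair count kept at the design depth the
    # paired test's power depends on
    return SimConfig(n_genes=1500, n_patients=60, n_survival_samples=300, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_paired_cohort(small_config)


@pytest.fixture(scope="session")
def small_prepped(small_cohort):
    cohort, truth = small_cohort
    prepped = log2_transform(quantile_normalize(cohort.expr))
    return PairedCohort(prepped, cohort.annotation, cohort.pairing), truth


@pytest.fixture(scope="session")
def small_de_sets(small_prepped):
    cohort, truth = small_prepped
    res = paired_differential(cohort)
    return {
        "res": res,
        "higher": select_differential(res, 0.001, "higher"),
        "lower": select_differential(res, 0.001, "lower"),
        "truth": truth,
    }
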