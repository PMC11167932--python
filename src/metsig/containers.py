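"""Core data containers shared across the pipeline.

Expression data travel as a genes × samples :class:`pandas.DataFrame` wrapped
in :class:`ExpressionMatrix`, which carries a units flag so that each stage can
assert it is operating on the scale it expects (raw TPM, log2, or gene-wise
standardized "sd" units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TPM = "tpm"
LOG2 = "log2"
SD_UNITS = "sd"

_VALID_UNITS = (TPM, LOG2, SD_UNITS)

ROLE_METASTASIS = "metastasis"
ROLE_PRIMARY = "primary"


class MetsigError(ValueError):
    """Base error for invalid inputs or configurations."""


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with a units flag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids.
    units
        One of ``"tpm"``, ``"log2"``, ``"sd"``.
    """

    values: pd.DataFrame
    units: str

    def __post_init__(self) -> None:
        if self.units not in _VALID_UNITS:
            raise MetsigError(f"unknown units {self.units!r}; expected one of {_VALID_UNITS}")
        if self.values.index.has_duplicates:
            raise MetsigError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise MetsigError("duplicate sample ids in expression matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_units(self, units: str) -> None:
        if self.units != units:
            raise MetsigError(f"expected {units} units, got {self.units}")

    def copy_with(self, values: pd.DataFrame, units: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.units if units is None else units)


def collapse_duplicate_genes(values: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene ids to the row with the highest mean value.

    Used at ingest time; the in-memory container forbids duplicates.
    """
    if not values.index.has_duplicates:
        return values
    means = values.mean(axis=1)
    order = np.argsort(-means.to_numpy(), kind="stable")
    deduped = values.iloc[order]
    deduped = deduped[~deduped.index.duplicated(keep="first")]
    return deduped.loc[values.index.drop_duplicates()]


@dataclass
class PairedCohort:
    """A paired metastasis/primary cohort.

    ``annotation`` is indexed by sample id with columns ``patient``, ``role``
    (``metastasis`` or ``primary``), ``site``, and optionally ``study`` and
    ``subtype``. ``pairing`` is indexed by patient id with columns
    ``metastasis`` and ``primary`` naming the two samples.
    """

    expr: ExpressionMatrix
    annotation: pd.DataFrame
    pairing: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        samples = set(self.expr.samples)
        unknown = set(self.annotation.index) - samples
        if unknown:
            raise MetsigError(f"annotation references unknown samples: {sorted(unknown)[:5]}")
        if self.pairing.index.has_duplicates:
            raise MetsigError("a patient appears more than once in the pairing")
        for col, role in ((ROLE_METASTASIS, ROLE_METASTASIS), (ROLE_PRIMARY, ROLE_PRIMARY)):
            if col not in self.pairing.columns:
                raise MetsigError(f"pairing lacks column {col!r}")
            for patient, sample in self.pairing[col].items():
                if sample not in samples:
                    raise MetsigError(f"pairing for patient {patient!r} references unknown sample {sample!r}")
                if self.annotation.loc[sample, "role"] != role:
                    raise MetsigError(
                        f"sample {sample!r} paired as {role} but annotated as "
                        f"{self.annotation.loc[sample, 'role']!r}"
                    )

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    def paired_differences(self) -> pd.DataFrame:
        """Per-gene, per-patient (metastasis − primary) differences."""
        met = self.expr.values[self.pairing[ROLE_METASTASIS]].to_numpy()
        pri = self.expr.values[self.pairing[ROLE_PRIMARY]].to_numpy()
        return pd.DataFrame(met - pri, index=self.expr.genes, columns=self.pairing.index)

    def metastasis_sites(self) -> pd.Series:
        """Biopsy site of each patient's metastasis sample, indexed by patient."""
        met_samples = self.pairing[ROLE_METASTASIS]
        sites = self.annotation.loc[met_samples, "site"]
        return pd.Series(sites.to_numpy(), index=self.pairing.index, name="site")


@dataclass
class ContingencyResult:
    """A 2×2 overlap table with its enrichment statistics.

    Cells: ``a`` = |A∩B|, ``b`` = |A\\B|, ``c`` = |B\\A|, ``d`` = rest of the
    universe. ``expected`` is the chance overlap |A||B|/N.
    """

    a: int
    b: int
    c: int
    d: int
    expected: float
    chi2: float
    chi2_p: float
    fisher_p: float
    odds_ratio: float
    zero_cell: bool = False

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_rounded(self) -> int:
        # round half away from zero, matching how the headline count is quoted
        return int(np.floor(self.expected + 0.5))

    def as_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "n": self.n,
            "expected": self.expected,
            "expected_rounded": self.expected_rounded,
            "chi2": self.chi2,
            "chi2_p": self.chi2_p,
            "fisher_p": self.fisher_p,
            "odds_ratio": self.odds_ratio,
            "zero_cell": self.zero_cell,
        }


@dataclass
class TruthTable:
    """Planted ground truth of a synthetic study.

    ``roles`` maps gene → one of ``intrinsic_met``, ``site_confounder``,
    ``breast_marker``, ``cell_cycle``, ``neutral``. ``site_genes`` maps each
    biopsy site to its confounder genes. Effect sizes are in log2 units.
    """

    roles: pd.Series
    effects: dict
    site_genes: dict
    subtype_centroids: pd.DataFrame
    survival_beta: float
    seed: int
    tf_targets: dict = field(default_factory=dict)
    knockdown_targets: dict = field(default_factory=dict)

    def genes_with_role(self, role: str) -> list:
        return list(self.roles.index[self.roles == role])

    def __post_init__(self) -> None:
        for key, value in self.effects.items():
            if not np.isfinite(value):
                raise MetsigError(f"non-finite planted effect {key}={value}")
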