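"""Plain-text readers and writers for the pipeline's interchange formats.

Expression matrices travel as TSV with genes as rows (first column the gene
id); gene sets as GMT (set name, description, then tab-separated genes);
genomic intervals as 6-column BED (0-based, half-open, strand in column 6);
survival tables as CSV with ``sample``, ``time``, ``event`` and optional
covariate columns.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, MetsigError, PairedCohort, collapse_duplicate_genes


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path, units: str) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values = collapse_duplicate_genes(values)
    return ExpressionMatrix(values, units)


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    out = annotation.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_pairing_tsv(pairing: pd.DataFrame, path: str | Path) -> None:
    out = pairing.copy()
    out.index.name = "patient"
    out.to_csv(path, sep="\t")


def read_pairing_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_paired_cohort(
    expression_path: str | Path,
    annotation_path: str | Path,
    pairing_path: str | Path,
    units: str,
) -> PairedCohort:
    return PairedCohort(
        read_expression_tsv(expression_path, units),
        read_annotation_tsv(annotation_path),
        read_pairing_tsv(pairing_path),
    )


def write_gmt(sets: dict[str, set], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gmt(path: str | Path) -> dict[str, set]:
    sets: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MetsigError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            name = fields[0]
            if name in sets:
                raise MetsigError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(g for g in fields[2:] if g)
    return sets


_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    out = intervals.copy()
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "+"
    out[_BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    rows = pd.read_csv(path, sep="\t", header=None, names=_BED_COLUMNS, usecols=range(6))
    bad = rows["end"] <= rows["start"]
    if bad.any():
        raise MetsigError(f"{path}: {int(bad.sum())} BED records with end <= start")
    return rows


def write_survival_csv(survival: pd.DataFrame, path: str | Path) -> None:
    out = survival.copy()
    out.index.name = "sample"
    out.to_csv(path)


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample")
    for col in ("time", "event"):
        if col not in df.columns:
            raise MetsigError(f"{path}: survival table lacks column {col!r}")
    if (df["time"] <= 0).any():
        raise MetsigError(f"{path}: survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise MetsigError(f"{path}: event indicator must be 0/1")
    return df


def write_truth_tsv(roles: pd.Series, path: str | Path) -> None:
    out = roles.to_frame("role")
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_truth_tsv(path: str | Path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0)["role"]
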