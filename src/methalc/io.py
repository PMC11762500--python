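"""Delimited-text formats for methylation matrices, cohort tables and run
configuration.

Matrix dialect: tab-separated UTF-8, '.' decimal, "NA" for missing; header
row of CpG identifiers, first column sample identifiers.  Values are written
with 17 significant digits so write -> read round-trips are lossless for
float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

_NA = "NA"


class MatrixParseError(ValueError):
    pass


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep=_NA, float_format="%.17g", index_label="sample_id")


def read_matrix(path) -> pd.DataFrame:
    """Read a samples x CpGs matrix, validating shape and identifiers."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise MatrixParseError(f"{path}: empty file")
        cols = header.split("\t")
        n_cols = len(cols)
        seen = set()
        dups = [c for c in cols[1:] if c in seen or seen.add(c)]
        if dups:
            raise MatrixParseError(f"{path}: duplicate CpG identifiers {dups[:5]}")
        for lineno, line in enumerate(fh, start=2):
            if line.rstrip("\n").count("\t") + 1 != n_cols:
                raise MatrixParseError(f"{path}: ragged row at line {lineno}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False)
    if df.shape[0] == 0:
        raise MatrixParseError(f"{path}: no data rows")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise MatrixParseError(f"{path}: duplicate sample identifiers {dups[:5]}")
    return df


#: cohort table column dictionary (written alongside by write_cohort)
COHORT_COLUMNS = {
    "units_last_week": "self-reported alcohol units consumed last week (NHS units)",
    "normal_week_flag": "last week vs habit: normal | more | less | unknown",
    "age": "age in years at blood draw",
    "sex": "F | M",
    "batch": "methylation processing batch index",
    "smoking_score": "smoking DNAm score (standardized)",
}


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", na_rep=_NA, float_format="%.17g", index_label="sample_id")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False)
    if df.shape[0] == 0:
        raise MatrixParseError(f"{path}: no data rows")
    return df


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; round-trips through YAML."""

    out_dir: str = "methalc_run"
    seed: int = 0
    # synthetic cohort (used when no matrix/cohort paths are given)
    n_samples: int = 1000
    n_cpgs: int = 500
    n_batches: int = 2
    arch: dict = field(default_factory=dict)       # EffectArchitecture overrides
    reporting: dict = field(default_factory=dict)  # ReportingModel overrides
    # optional external inputs
    matrix_path: str | None = None
    cohort_path: str | None = None
    preselect_path: str | None = None  # newline-delimited CpG ids
    # stage toggles
    run_grid: bool = True
    run_final_model: bool = True
    run_ewas: bool = True
    run_assoc: bool = True
    # stage parameters
    train_fraction: float = 0.52
    episcore: dict = field(default_factory=dict)  # train_elastic_net kwargs
    bayesr: dict = field(default_factory=dict)    # BayesRConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def read_cpg_list(path) -> list:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_cpg_list(cpgs, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.writelines(f"{c}\n" for c in cpgs)
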