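"""CSV interchange for feature tables, labels, CCC vectors and studies.

All tabular artifacts are plain CSV. Feature tables have a `sample_id`
first column and one column per feature; values round-trip at 15
significant digits. A CCC vector is a two-column CSV (`feature`, `ccc`)
where an undefined CCC serializes as an empty field.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ReplicateStudy

_FLOAT_FMT = "%.15g"


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index_label="sample_id", float_format=_FLOAT_FMT)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id", float_precision="round_trip")
    if df.isna().any().any():
        bad = sorted(df.columns[df.isna().any()])
        raise ValueError(f"feature table {path} contains missing values in {bad}")
    return df


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("label").to_csv(path, index_label="sample_id")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, index_col="sample_id")
    return df["label"].astype(np.int64)


def write_ccc_vector(ccc: pd.Series, path) -> None:
    out = ccc.rename("ccc").rename_axis("feature")
    out.to_csv(path, float_format=_FLOAT_FMT, na_rep="")


def read_ccc_vector(path) -> pd.Series:
    df = pd.read_csv(path, index_col="feature", float_precision="round_trip")
    return df["ccc"]


_STUDY_FILES = {
    "train_rep1": "train_rep1.csv",
    "train_rep2": "train_rep2.csv",
    "train_labels": "train_labels.csv",
    "test_features": "test_features.csv",
    "test_labels": "test_labels.csv",
}


def write_study(study: ReplicateStudy, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_feature_table(study.train_rep1, d / _STUDY_FILES["train_rep1"])
    write_feature_table(study.train_rep2, d / _STUDY_FILES["train_rep2"])
    write_labels(study.train_labels, d / _STUDY_FILES["train_labels"])
    write_feature_table(study.test_features, d / _STUDY_FILES["test_features"])
    write_labels(study.test_labels, d / _STUDY_FILES["test_labels"])


def read_study(directory) -> ReplicateStudy:
    d = Path(directory)
    return ReplicateStudy(
        train_rep1=read_feature_table(d / _STUDY_FILES["train_rep1"]),
        train_rep2=read_feature_table(d / _STUDY_FILES["train_rep2"]),
        train_labels=read_labels(d / _STUDY_FILES["train_labels"]),
        test_features=read_feature_table(d / _STUDY_FILES["test_features"]),
        test_labels=read_labels(d / _STUDY_FILES["test_labels"]),
    )
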