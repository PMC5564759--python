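"""Tab-separated readers and writers for the pipeline's tables.

All tables are UTF-8 TSV with a header row; missing values are encoded
"NA". Reading a matrix with duplicated gene or sample identifiers is a
parse error naming the offending id — silent duplicate collapse would
corrupt every downstream correlation.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_survival",
    "write_survival",
    "write_edges",
    "read_edges",
    "write_json_report",
    "read_json_report",
]


class TableParseError(ValueError):
    pass


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a row-id x column-id numeric TSV matrix (e.g. genes x samples)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    counts = pd.Series(header[1:]).value_counts()
    dup_cols = list(counts.index[counts > 1])
    if dup_cols:
        raise TableParseError(f"{path}: duplicated column id(s): {dup_cols}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    dup_rows = df.index[df.index.duplicated()].unique()
    if len(dup_rows):
        raise TableParseError(f"{path}: duplicated row id(s): {list(dup_rows)}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label=index_label)


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    required = {"sample", "time", "event", "group"}
    missing = required - set(df.columns)
    if missing:
        raise TableParseError(f"{path}: missing column(s) {sorted(missing)}")
    if (df["time"] < 0).any():
        raise TableParseError(f"{path}: negative survival times")
    return df


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index=False)


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", na_rep="NA", index=False)


def read_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("source", "target", "weight"):
        if col not in df.columns:
            raise TableParseError(f"{path}: missing column {col!r}")
    return df


def write_json_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
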