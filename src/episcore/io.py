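"""Tabular I/O helpers.

All expression matrices are TSV with probe-set IDs as the index (rows) and
sample IDs as the header (columns), linear-scale positive signals.  Phenotype
and survival tables are TSV with a ``sample_id`` column.
"""
from __future__ import annotations

import pandas as pd


def read_expression(path) -> pd.DataFrame:
    """Read a probes × samples expression matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"expression matrix {path!r} has no sample columns")
    return df


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_phenotype(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"phenotype table {path!r} lacks a 'sample_id' column")
    return df.set_index("sample_id")


def write_phenotype(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index_label="sample_id")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
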