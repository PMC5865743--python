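"""Readers and writers for the pipeline's tabular formats.

Expression TSV: first column is the feature id (miRNA or gene), header row
holds sample ids, values are non-negative FPKM-like reals.  Clinical TSV:
``sample_id``, ``time_months``, ``event``.  Readers validate and report
alignment mismatches instead of silently reindexing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

CLINICAL_COLUMNS = ("sample_id", "time_months", "event")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features × samples expression matrix; average duplicate sample columns."""
    # read the header by hand so duplicate sample columns survive (pandas
    # would mangle them to "s", "s.1", defeating duplicate averaging)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    df = pd.read_csv(path, sep="\t", skiprows=1, header=None, index_col=0)
    df.columns = [str(c) for c in header[1:]]
    df.index = df.index.astype(str)
    if df.columns.duplicated().any():
        df = df.T.groupby(level=0, sort=False).mean().T
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in {path}: {dups[:5]}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"missing expression values in {path}")
    if (values < 0).any():
        raise ValueError(f"negative expression values in {path}")
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in clin.columns]
    if missing:
        raise ValueError(f"clinical table {path} missing columns: {missing}")
    clin = clin.loc[:, list(CLINICAL_COLUMNS)]
    if clin["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample ids in clinical table {path}")
    if not np.isfinite(clin["time_months"].to_numpy(float)).all():
        raise ValueError(f"non-finite survival times in {path}")
    if (clin["time_months"] < 0).any():
        raise ValueError(f"negative survival times in {path}")
    if not clin["event"].isin([0, 1]).all():
        raise ValueError(f"event indicator outside {{0,1}} in {path}")
    return clin.reset_index(drop=True)


def write_clinical_tsv(clin: pd.DataFrame, path: str | Path) -> None:
    clin.loc[:, list(CLINICAL_COLUMNS)].to_csv(path, sep="\t", index=False)


def align_expression(expr: pd.DataFrame, clin: pd.DataFrame) -> pd.DataFrame:
    """Column-subset an expression matrix to the clinical samples, in clinical order."""
    missing = [s for s in clin["sample_id"] if s not in expr.columns]
    if missing:
        raise ValueError(
            f"{len(missing)} clinical samples absent from expression matrix "
            f"(first: {missing[:5]})"
        )
    return expr.loc[:, list(clin["sample_id"])]
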