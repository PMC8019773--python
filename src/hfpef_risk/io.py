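"""Readers and writers for the pipeline's plain-text formats.

An expression matrix is a genes x samples pandas DataFrame (gene ids in the
index, sample ids in the columns) read from TSV; phenotypes are a CSV with
columns sample_id, outcome (good/poor), time (years), event (0/1), returned
as a DataFrame indexed by sample_id with outcome coded poor = 1 (the positive
class is the rare death class).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OUTCOME_CODES = {"good": 0, "poor": 1}


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"empty expression matrix: {path}")
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate gene id(s): {', '.join(map(str, dup[:5]))}")
    dup_s = df.columns[df.columns.duplicated()].unique()
    if len(dup_s):
        raise ValueError(f"duplicate sample id(s): {', '.join(map(str, dup_s[:5]))}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        bad = df.map(lambda v: not _is_number(v))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        ) from None
    out = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))
    logger.info("read expression matrix: %d genes x %d samples", *out.shape)
    return out


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_expression_matrix(X: pd.DataFrame, path) -> None:
    # %.17g round-trips IEEE doubles exactly
    X.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype CSV; outcome recoded to poor=1, good=0."""
    df = pd.read_csv(path)
    required = {"sample_id", "outcome", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file missing column(s): {sorted(missing)}")
    unknown = set(df["outcome"].astype(str)) - set(OUTCOME_CODES)
    if unknown:
        raise ValueError(f"unrecognized outcome value(s): {sorted(unknown)}")
    if (df["time"] < 0).any():
        bad = df.loc[df["time"] < 0, "sample_id"].tolist()
        raise ValueError(f"negative survival time for sample(s): {bad}")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    out = pd.DataFrame(
        {
            "outcome": df["outcome"].map(OUTCOME_CODES).to_numpy(),
            "time": df["time"].to_numpy(dtype=float),
            "event": df["event"].to_numpy(dtype=int),
        },
        index=pd.Index(df["sample_id"].astype(str), name="sample_id"),
    )
    if out.index.duplicated().any():
        raise ValueError("duplicate sample_id in phenotype file")
    return out


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    inv = {v: k for k, v in OUTCOME_CODES.items()}
    out = pheno.copy()
    out["outcome"] = out["outcome"].map(inv)
    out.to_csv(path, index_label="sample_id", float_format="%.17g")


def align_samples(X: pd.DataFrame, pheno: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Check expression and phenotype sample ids match; return in a common order."""
    expr_ids, ph_ids = set(X.columns), set(pheno.index)
    if expr_ids != ph_ids:
        only_e = sorted(expr_ids - ph_ids)[:5]
        only_p = sorted(ph_ids - expr_ids)[:5]
        raise ValueError(
            f"sample mismatch: in expression only {only_e}, in phenotypes only {only_p}"
        )
    order = list(X.columns)
    return X, pheno.loc[order]
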