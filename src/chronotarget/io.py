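"""Readers, writers and small numeric utilities shared by the pipeline.

All tables travel as TSV with a ``# schema:`` header comment so outputs are
self-describing and round-trip stable. Gene identifiers are opaque strings
(HGNC symbols in practice); time columns are ``CT<hours>`` labels, with an
optional ``_r<k>`` replicate suffix.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .rhythm import parse_time_columns

__all__ = [
    "read_expression_tsv",
    "write_table",
    "read_table",
    "read_gene_list",
    "write_gene_list",
    "pca_project",
]


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    """Write a TSV with a schema header comment declaring the columns."""
    path = Path(path)
    index_label = index_label or (df.index.name or "id")
    with open(path, "w") as fh:
        fh.write("# schema: " + "\t".join([index_label, *map(str, df.columns)]) + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_expression_tsv(path) -> pd.DataFrame:
    """Read and validate a temporal expression matrix.

    First column: gene id; remaining columns ``CT<hours>`` (optionally with
    replicate suffixes). Duplicate gene ids and negative values are errors;
    out-of-order time columns are reordered with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate gene id(s) in {path}: {list(map(str, dup[:5]))}")
    vals = df.to_numpy(dtype=float)
    if np.any(vals[np.isfinite(vals)] < 0):
        rows = df.index[(df < 0).any(axis=1)]
        raise ValueError(f"negative expression values at gene(s) {list(map(str, rows[:5]))}")
    times, _ = parse_time_columns(df.columns)  # raises on unparseable labels
    order = np.argsort(times, kind="stable")
    if not np.all(order == np.arange(len(order))):
        warnings.warn(f"time columns out of order in {path}; reordered", stacklevel=2)
        df = df.iloc[:, order]
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return df


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        fh.writelines(f"{g}\n" for g in genes)


def pca_project(matrix: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples (columns) onto the top-k principal components.

    Features (genes) are centered and scaled to unit variance across
    samples; zero-variance features are dropped with a warning. Returns
    sample coordinates (samples x k) and the variance-explained fractions.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    X = matrix.to_numpy(dtype=float).T  # samples x features
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} zero-variance features dropped", stacklevel=2)
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(k, len(s))
    coords = u[:, :k] * s[:k]
    var_frac = (s**2 / np.sum(s**2))[:k]
    out = pd.DataFrame(coords, index=matrix.columns, columns=[f"PC{i+1}" for i in range(k)])
    return out, var_frac
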