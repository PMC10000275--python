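"""Tab-delimited readers and writers for matrices, metadata and result tables.

Counts and expression matrices are genes x samples: first column the gene id,
header row the sample ids. A sparse triplet format (MatrixMarket-style
coordinate text) is available for large count matrices.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_meta",
    "write_meta",
    "write_table",
    "read_counts_mtx",
    "write_counts_mtx",
]


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "gene_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label=meta.index.name or "sample_id")


def read_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    """Write counts as coordinate-format MatrixMarket plus gene/sample id lists."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.coo_matrix(counts.to_numpy()))
    prefix.with_suffix(".genes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
    prefix.with_suffix(".samples.txt").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(prefix) -> pd.DataFrame:
    prefix = Path(prefix)
    m = spio.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    samples = prefix.with_suffix(".samples.txt").read_text().splitlines()
    return pd.DataFrame(np.asarray(m), index=genes, columns=samples)
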