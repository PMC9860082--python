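"""Reading and writing count matrices and sidecar tables.

Matrices are stored cells-as-rows.  The sparse on-disk layout is Matrix
Market (``matrix.mtx``) with ``genes.tsv`` and ``barcodes.tsv``
sidecars (one identifier per line); dense matrices are TSV with
barcodes as the index column and genes as the header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .preprocess import _dense

__all__ = ["read_counts", "write_counts", "read_labels", "write_labels"]

MTX_FILES = ("matrix.mtx", "genes.tsv", "barcodes.tsv")


def _check_unique(ids: Sequence[str], what: str, path: Path) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dupes = s[s.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what} in {path}: {dupes}")


def read_counts(path: str | Path, format: str = "mtx") -> ad.AnnData:
    """Load a UMI count matrix with aligned cell/gene identifiers.

    ``format="mtx"``: ``path`` is a directory holding matrix.mtx,
    genes.tsv and barcodes.tsv.  ``format="dense"``: ``path`` is a TSV
    with barcodes in the first column and genes in the header.
    """
    path = Path(path)
    if format == "mtx":
        mtx, genes_f, barcodes_f = (path / f for f in MTX_FILES)
        for f in (mtx, genes_f, barcodes_f):
            if not f.exists():
                raise FileNotFoundError(f)
        M = sp.csr_matrix(scipy.io.mmread(mtx))
        genes = genes_f.read_text().splitlines()
        genes = [g.split("\t")[0] for g in genes if g]
        barcodes = [b for b in barcodes_f.read_text().splitlines() if b]
        if M.shape != (len(barcodes), len(genes)):
            raise ValueError(
                f"matrix is {M.shape[0]} x {M.shape[1]} but sidecars list "
                f"{len(barcodes)} barcodes and {len(genes)} genes"
            )
        _check_unique(barcodes, "barcodes", barcodes_f)
        _check_unique(genes, "genes", genes_f)
        X = M.toarray()
    elif format == "dense":
        df = pd.read_csv(path, sep="\t", index_col=0)
        _check_unique(list(df.index), "barcodes", path)
        _check_unique(list(df.columns), "genes", path)
        barcodes, genes = list(df.index.astype(str)), list(df.columns.astype(str))
        X = df.to_numpy()
    else:
        raise ValueError(f"unknown format: {format!r}")
    if not np.issubdtype(X.dtype, np.number) or (X < 0).any():
        raise ValueError("count matrix must be non-negative and numeric")
    if not np.allclose(X, np.round(X)):
        raise ValueError("count matrix must be integer-valued")
    return ad.AnnData(
        X=X.astype(np.int64),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def write_counts(adata: ad.AnnData, path: str | Path, format: str = "mtx") -> Path:
    """Write a count matrix; inverse of :func:`read_counts`."""
    path = Path(path)
    X = _dense(adata.X)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(X), field="integer")
        (path / "genes.tsv").write_text("\n".join(adata.var_names) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    elif format == "dense":
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(X, index=adata.obs_names, columns=adata.var_names).to_csv(
            path, sep="\t"
        )
    else:
        raise ValueError(f"unknown format: {format!r}")
    return path


def read_labels(path: str | Path, value_column: str | None = None) -> pd.Series:
    """Read a per-cell label/metadata table (TSV, cell id first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValueError(f"no label column in {path}")
    col = value_column or df.columns[0]
    return df[col]


def write_labels(labels: pd.Series, path: str | Path, name: str = "label") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels.rename(name).rename_axis("cell_id").to_csv(path, sep="\t")
    return path
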