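"""QC filtering, log-library-size normalization, and feature selection.

Normalization convention: entry(c, g) = ln(1 + scale_factor * count(c, g)
/ libsize(c)) with natural log and scale_factor 10,000 by default.  The
default QC thresholds are package configuration values, not measured
properties of any particular dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "QCThresholds",
    "QCReport",
    "FeatureSet",
    "filter_cells",
    "normalize_log_library",
    "select_features",
]

DEFAULT_SCALE_FACTOR = 10_000.0


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if sp.issparse(X) else X)


@dataclass(frozen=True)
class QCThresholds:
    """Cell- and gene-level QC cutoffs.

    Cells must reach ``min_umis_per_cell`` total UMIs and
    ``min_genes_per_cell`` detected genes (and, when a mito gene list is
    supplied, stay below ``max_mito_fraction``); genes must be detected
    in at least ``min_cells_per_gene`` retained cells.
    """

    min_umis_per_cell: int = 1000
    min_genes_per_cell: int = 500
    max_mito_fraction: float | None = None
    min_cells_per_gene: int = 0

    def validate(self) -> None:
        for name in ("min_umis_per_cell", "min_genes_per_cell", "min_cells_per_gene"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"QCThresholds.{name} must be a finite non-negative integer")
        if self.max_mito_fraction is not None and not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("QCThresholds.max_mito_fraction must lie in [0, 1]")


@dataclass
class QCReport:
    """Per-criterion removal counts and per-group QC means."""

    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    removed_by: dict[str, int] = field(default_factory=dict)
    group_summary: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("cells_in", self.n_cells_in),
            ("cells_out", self.n_cells_out),
            ("genes_in", self.n_genes_in),
            ("genes_out", self.n_genes_out),
        ] + [(f"removed_{k}", v) for k, v in self.removed_by.items()]
        return pd.DataFrame(rows, columns=["criterion", "count"])


def filter_cells(
    adata: ad.AnnData,
    thresholds: QCThresholds,
    mito_genes: Sequence[str] | None = None,
    group_keys: Sequence[str] | None = None,
) -> tuple[ad.AnnData, QCReport]:
    """Apply QC thresholds, cells first and then genes, iterated to a
    fixed point so that re-applying the same thresholds is a no-op.

    Returns the filtered copy and a QCReport with per-criterion removal
    counts and, for each ``group_keys`` column in ``adata.obs``
    (e.g. time point, line), mean UMIs and mean detected genes.
    """
    thresholds.validate()
    X = _dense(adata.X)
    if X.size and X.min() < 0:
        raise ValueError("count matrix contains negative entries")
    if thresholds.max_mito_fraction is not None and mito_genes is None:
        raise ValueError("max_mito_fraction set but no mito gene list given")

    mito_mask = (
        adata.var_names.isin(mito_genes) if mito_genes is not None else None
    )
    removed = {"low_umis": 0, "low_genes": 0, "high_mito": 0, "low_gene_support": 0}
    cell_keep = np.ones(adata.n_obs, dtype=bool)
    gene_keep = np.ones(adata.n_vars, dtype=bool)

    while True:
        sub = X[np.ix_(cell_keep, gene_keep)]
        umis = sub.sum(axis=1)
        n_genes = (sub > 0).sum(axis=1)
        ok = np.ones(sub.shape[0], dtype=bool)
        fail_umi = umis < thresholds.min_umis_per_cell
        fail_genes = n_genes < thresholds.min_genes_per_cell
        removed["low_umis"] += int(fail_umi.sum())
        removed["low_genes"] += int((fail_genes & ~fail_umi).sum())
        ok &= ~fail_umi & ~fail_genes
        if thresholds.max_mito_fraction is not None:
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = sub[:, mito_mask[gene_keep]].sum(axis=1) / np.where(umis > 0, umis, 1)
            fail_mito = frac > thresholds.max_mito_fraction
            removed["high_mito"] += int((fail_mito & ok).sum())
            ok &= ~fail_mito
        new_cell = cell_keep.copy()
        new_cell[np.flatnonzero(cell_keep)[~ok]] = False

        sub2 = X[np.ix_(new_cell, gene_keep)]
        support = (sub2 > 0).sum(axis=0)
        gene_ok = support >= thresholds.min_cells_per_gene
        removed["low_gene_support"] += int((~gene_ok).sum())
        new_gene = gene_keep.copy()
        new_gene[np.flatnonzero(gene_keep)[~gene_ok]] = False

        changed = (new_cell != cell_keep).any() or (new_gene != gene_keep).any()
        cell_keep, gene_keep = new_cell, new_gene
        if not changed:
            break

    if not cell_keep.any():
        warnings.warn("QC filtering removed every cell", stacklevel=2)

    out = adata[cell_keep, gene_keep].copy()
    group_summary = None
    if group_keys:
        Xo = _dense(out.X)
        df = out.obs[list(group_keys)].copy()
        df["mean_umis"] = Xo.sum(axis=1)
        df["mean_detected_genes"] = (Xo > 0).sum(axis=1)
        group_summary = (
            df.groupby(list(group_keys), observed=True)[["mean_umis", "mean_detected_genes"]]
            .mean()
            .reset_index()
        )
    report = QCReport(
        n_cells_in=adata.n_obs,
        n_cells_out=out.n_obs,
        n_genes_in=adata.n_vars,
        n_genes_out=out.n_vars,
        removed_by=removed,
        group_summary=group_summary,
    )
    return out, report


def normalize_log_library(
    adata: ad.AnnData, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> ad.AnnData:
    """Log-library-size normalization.

    entry(c, g) = ln(1 + scale_factor * count(c, g) / libsize(c)),
    where libsize(c) is the cell's total UMI count.  Exactly
    zero-preserving and invariant to rescaling a cell's counts.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    X = _dense(adata.X).astype(float)
    libsize = X.sum(axis=1)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        names = ", ".join(adata.obs_names[zero[:5]])
        raise ValueError(f"cells with zero library size cannot be normalized: {names}")
    norm = np.log1p(scale_factor * X / libsize[:, None])
    out = ad.AnnData(X=norm, obs=adata.obs.copy(), var=adata.var.copy())
    for key, val in adata.obsm.items():
        out.obsm[key] = val
    out.uns["normalization"] = {
        "method": "log_library_size",
        "scale_factor": float(scale_factor),
        "log_base": "e",
        "source_shape": [int(adata.n_obs), int(adata.n_vars)],
    }
    return out


@dataclass(frozen=True)
class FeatureSet:
    """Ordered gene list shared by reference and query."""

    genes: tuple[str, ...]
    method: str

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("FeatureSet must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("FeatureSet contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def select_features(
    ref_genes: Iterable[str],
    query_genes: Iterable[str],
    mode: str = "intersection",
    k: int | None = None,
    ref_norm: ad.AnnData | None = None,
    panel: Sequence[str] | None = None,
) -> FeatureSet:
    """Select the gene space used for classification.

    intersection : sorted genes common to reference and query;
    hvg : top-k by variance of normalized expression in the reference,
        restricted to the intersection (requires ``ref_norm`` and ``k``);
    markers : user panel intersected with both gene universes.
    """
    ref = list(ref_genes)
    qry = set(query_genes)
    common = sorted(g for g in set(ref) if g in qry)
    if not common:
        raise ValueError("reference and query share no genes")
    if mode == "intersection":
        genes = common
    elif mode == "hvg":
        if ref_norm is None or k is None:
            raise ValueError("mode='hvg' requires ref_norm and k")
        if k >= len(common):
            warnings.warn(
                f"k={k} >= intersection size {len(common)}; returning whole intersection",
                stacklevel=2,
            )
            genes = common
        else:
            Xn = _dense(ref_norm[:, common].X)
            var = pd.Series(Xn.var(axis=0), index=common)
            # variance descending, gene name as deterministic tie-break
            order = sorted(common, key=lambda g: (-var[g], g))
            genes = sorted(order[:k])
    elif mode == "markers":
        if panel is None:
            raise ValueError("mode='markers' requires a panel")
        genes = [g for g in panel if g in common]
        if not genes:
            raise ValueError("marker panel shares no genes with reference and query")
    else:
        raise ValueError(f"unknown feature-selection mode: {mode!r}")
    return FeatureSet(genes=tuple(genes), method=mode)
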