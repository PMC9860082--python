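"""Synthetic reference atlases and query differentiation datasets.

The generator emulates the structure of a labeled ventral-midbrain
reference atlas (distinct cell types, each defined by a marker-gene
program) and of hESC-derived query cells, which may be pure instances of
one reference program or convex mixtures of several (transitional
progenitors that partially share two identities).

Count model: each gene g has a lognormal baseline propensity lambda_g;
a type's markers are up-regulated by a factor 2**marker_log2fc; a type
"program" is the propensity vector renormalized to sum to one.  A cell
with library size L (lognormal) and program p has UMI counts drawn
negative-binomially with mean L * p_g and size (inverse-overdispersion)
``nb_dispersion``.  Every draw is reproducible from the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "AtlasSpec",
    "QuerySpec",
    "GroundTruth",
    "DEFAULT_TYPE_NAMES",
    "generate_atlas",
    "generate_query",
    "one_hot_weights",
    "mixed_weights",
]

#: Ventral-midbrain-style reference vocabulary used when naming synthetic
#: types (radial glia, progenitors, neuroblasts, DA neurons, off-target
#: classes); beyond 15 types generic names are appended.
DEFAULT_TYPE_NAMES = (
    "Rgl1", "Rgl3", "ProgM", "ProgFPM", "ProgFPL", "NProg", "NbM",
    "NbML1", "DA0", "DA1", "DA2", "RN", "OMTN", "Sert", "VLMC",
)

SIMPLEX_ATOL = 1e-9


def _type_names(n_types: int) -> list[str]:
    names = list(DEFAULT_TYPE_NAMES[:n_types])
    names += [f"Type{i}" for i in range(len(names), n_types)]
    return names


@dataclass(frozen=True)
class AtlasSpec:
    """Parameters of a synthetic labeled reference atlas."""

    n_types: int = 10
    n_cells_per_type: int = 200
    n_genes: int = 2000
    n_markers_per_type: int = 30
    marker_log2fc: float = 3.0
    baseline_mean_log: float = 0.0
    baseline_sd_log: float = 1.0
    nb_dispersion: float = 2.0
    libsize_mean_log: float = math.log(10_000.0)
    libsize_sd_log: float = 0.3
    n_shared_markers: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_types", "n_cells_per_type", "n_genes", "n_markers_per_type"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"AtlasSpec.{name} must be a positive integer")
        if self.marker_log2fc < 0:
            raise ValueError("AtlasSpec.marker_log2fc must be >= 0")
        for name in ("baseline_sd_log", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"AtlasSpec.{name} must be strictly positive")
        if self.libsize_sd_log < 0:
            raise ValueError("AtlasSpec.libsize_sd_log must be >= 0")
        if self.n_shared_markers < 0:
            raise ValueError("AtlasSpec.n_shared_markers must be >= 0")
        needed = self.n_markers_per_type * self.n_types + self.n_shared_markers
        if needed > self.n_genes:
            raise ValueError(
                "AtlasSpec.n_markers_per_type: disjoint marker sets need "
                f"{needed} genes but n_genes={self.n_genes}"
            )


@dataclass(frozen=True)
class QuerySpec:
    """Parameters of a synthetic query ("differentiation") dataset.

    ``program_weights`` has one row per cell giving its mixing weights
    over the atlas's type vocabulary; each row must lie on the
    probability simplex.  Pure cells are one-hot rows; transitional
    cells carry mass on two or more types.
    """

    program_weights: np.ndarray
    nb_dispersion: float = 2.0
    libsize_mean_log: float = math.log(10_000.0)
    libsize_sd_log: float = 0.3
    timepoint_labels: Sequence[str] | None = None
    line_labels: Sequence[str] | None = None
    line_libsize_log_shift: Mapping[str, float] | None = None
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return int(np.asarray(self.program_weights).shape[0])

    def validate(self, n_types: int) -> None:
        w = np.asarray(self.program_weights, dtype=float)
        if w.ndim != 2 or (w.size and w.shape[1] != n_types):
            raise ValueError(
                f"QuerySpec.program_weights must be (n_cells, {n_types}), got {w.shape}"
            )
        if w.size:
            if (w < 0).any():
                raise ValueError("QuerySpec.program_weights has negative entries")
            if not np.allclose(w.sum(axis=1), 1.0, atol=SIMPLEX_ATOL):
                raise ValueError("QuerySpec.program_weights rows must sum to 1")
        if self.nb_dispersion <= 0:
            raise ValueError("QuerySpec.nb_dispersion must be strictly positive")
        if self.libsize_sd_log < 0:
            raise ValueError("QuerySpec.libsize_sd_log must be >= 0")
        for name in ("timepoint_labels", "line_labels"):
            lab = getattr(self, name)
            if lab is not None and len(lab) != self.n_cells:
                raise ValueError(f"QuerySpec.{name} length != n_cells")


@dataclass
class GroundTruth:
    """Generative truth of a synthetic dataset.

    dominant_type : per-cell argmax of the weight vector (ties broken by
        lowest type index);
    weights : per-cell full mixing-weight matrix (cells x types);
    marker_of : per-gene type whose marker program it belongs to ("" if
        none);
    programs : types x genes relative-expression programs (rows sum to 1).
    """

    type_names: list[str]
    gene_names: list[str]
    dominant_type: np.ndarray
    weights: np.ndarray
    marker_of: pd.Series
    programs: np.ndarray = field(repr=False)

    def markers_of(self, type_name: str) -> list[str]:
        return list(self.marker_of.index[self.marker_of == type_name])


def _dominant(weights: np.ndarray, type_names: Sequence[str]) -> np.ndarray:
    # np.argmax returns the first (lowest-index) maximum, the tie rule we want
    if weights.shape[0] == 0:
        return np.asarray([], dtype=object)
    return np.asarray([type_names[j] for j in np.argmax(weights, axis=1)], dtype=object)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(np.int64)


def generate_atlas(spec: AtlasSpec) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a labeled reference atlas of UMI counts.

    Returns an AnnData of shape (n_types * n_cells_per_type, n_genes)
    with ``obs["cell_type"]`` labels, plus the generative GroundTruth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    K, G = spec.n_types, spec.n_genes
    type_names = _type_names(K)
    gene_names = [f"G{g:05d}" for g in range(G)]

    baseline = rng.lognormal(spec.baseline_mean_log, spec.baseline_sd_log, G)
    perm = rng.permutation(G)
    m = spec.n_markers_per_type
    shared = perm[K * m : K * m + spec.n_shared_markers]

    marker_of = pd.Series([""] * G, index=gene_names, name="marker_of")
    programs = np.empty((K, G))
    fc = 2.0 ** spec.marker_log2fc
    for t in range(K):
        markers = perm[t * m : (t + 1) * m]
        prop = baseline.copy()
        prop[markers] *= fc
        if shared.size:
            prop[shared] *= fc
        programs[t] = prop / prop.sum()
        marker_of.iloc[markers] = type_names[t]

    n = K * spec.n_cells_per_type
    labels = np.repeat(type_names, spec.n_cells_per_type)
    libsize = rng.lognormal(spec.libsize_mean_log, spec.libsize_sd_log, n)
    counts = np.empty((n, G), dtype=np.int64)
    for t in range(K):
        rows = slice(t * spec.n_cells_per_type, (t + 1) * spec.n_cells_per_type)
        mu = libsize[rows, None] * programs[t][None, :]
        counts[rows] = _nb_counts(rng, mu, spec.nb_dispersion)

    weights = np.zeros((n, K))
    weights[np.arange(n), np.repeat(np.arange(K), spec.n_cells_per_type)] = 1.0

    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(
            {"cell_type": pd.Categorical(labels, categories=type_names)},
            index=[f"ref_{i:05d}" for i in range(n)],
        ),
        var=pd.DataFrame({"marker_of": marker_of.values}, index=gene_names),
    )
    adata.obsm["true_weights"] = weights
    truth = GroundTruth(
        type_names=type_names,
        gene_names=gene_names,
        dominant_type=_dominant(weights, type_names),
        weights=weights,
        marker_of=marker_of,
        programs=programs,
    )
    return adata, truth


def generate_query(atlas_truth: GroundTruth, spec: QuerySpec) -> tuple[ad.AnnData, GroundTruth]:
    """Draw query cells whose expected expression is a weight-mixture of
    the atlas's type programs."""
    K = len(atlas_truth.type_names)
    spec.validate(K)
    rng = np.random.default_rng(spec.seed)
    w = np.asarray(spec.program_weights, dtype=float).reshape(spec.n_cells, K)
    n, G = spec.n_cells, len(atlas_truth.gene_names)

    log_libsize = rng.normal(spec.libsize_mean_log, spec.libsize_sd_log, n)
    if spec.line_libsize_log_shift and spec.line_labels is not None:
        shift = np.asarray(
            [spec.line_libsize_log_shift.get(l, 0.0) for l in spec.line_labels]
        )
        log_libsize = log_libsize + shift
    libsize = np.exp(log_libsize)

    programs = w @ atlas_truth.programs  # rows still sum to 1
    mu = libsize[:, None] * programs
    counts = (
        _nb_counts(rng, mu, spec.nb_dispersion)
        if n
        else np.zeros((0, G), dtype=np.int64)
    )

    obs = pd.DataFrame(index=[f"query_{i:05d}" for i in range(n)])
    if spec.timepoint_labels is not None:
        obs["timepoint"] = list(spec.timepoint_labels)
    if spec.line_labels is not None:
        obs["line"] = list(spec.line_labels)
    dominant = _dominant(w, atlas_truth.type_names)
    obs["true_type"] = dominant

    adata = ad.AnnData(
        X=counts,
        obs=obs,
        var=pd.DataFrame(index=list(atlas_truth.gene_names)),
    )
    adata.obsm["true_weights"] = w
    truth = GroundTruth(
        type_names=list(atlas_truth.type_names),
        gene_names=list(atlas_truth.gene_names),
        dominant_type=dominant,
        weights=w,
        marker_of=atlas_truth.marker_of,
        programs=atlas_truth.programs,
    )
    return adata, truth


def one_hot_weights(n_cells: int, n_types: int, type_index: int) -> np.ndarray:
    """Pure-program weight rows: all mass on one type."""
    w = np.zeros((n_cells, n_types))
    w[:, type_index] = 1.0
    return w


def mixed_weights(
    n_cells: int, n_types: int, type_a: int, type_b: int, weight_a: float = 0.5
) -> np.ndarray:
    """Two-type mixture rows (transitional identity)."""
    if not 0.0 <= weight_a <= 1.0:
        raise ValueError("weight_a must be in [0, 1]")
    w = np.zeros((n_cells, n_types))
    w[:, type_a] = weight_a
    w[:, type_b] += 1.0 - weight_a
    return w
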