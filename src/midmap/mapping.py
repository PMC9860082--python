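"""Logistic-regression reference mapping and identity-quality scoring.

A one-vs-rest L2-regularized logistic classifier is trained on a
labeled reference atlas of log-normalized expression; query cells are
scored with each type's sigmoid and the per-type scores renormalized to
a probability vector on the simplex.  Per-cluster similarity is the
mean probability of the cluster's assigned (argmax) type, banded as
moderate [0.5, 0.8) or high [0.8, 1.0]; the wheel (polygon) layout
places the reference types on the unit circle and each cell at the
probability-weighted average of the vertices.

The one-vs-rest scheme (rather than a multinomial softmax) is a
deliberate convention: per-type scores are read as independent class
memberships before renormalization.  A multinomial alternative is
available via ``scheme="multinomial"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy.special import expit, softmax
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .clustering import ClusterPartition
from .preprocess import FeatureSet, _dense

__all__ = [
    "ClassifierModel",
    "ClusterSimilarity",
    "WheelLayout",
    "fit_classifier",
    "predict_probabilities",
    "score_clusters",
    "wheel_coordinates",
    "top_coefficient_genes",
    "plot_wheel",
]

HIGH_BAND = 0.8
SHOW_BAND = 0.5


@dataclass
class ClassifierModel:
    """Per-type logistic weights over a shared feature set."""

    weights: np.ndarray  # n_types x n_features
    intercepts: np.ndarray  # n_types
    features: tuple[str, ...]
    classes: tuple[str, ...]
    l2_strength: float
    scheme: str = "one-vs-rest"
    normalization: str = "log_library_size"
    converged: bool = True

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.weights.shape != (len(self.classes), len(self.features)):
            raise ValueError(
                f"weight matrix shape {self.weights.shape} != "
                f"(n_types={len(self.classes)}, n_features={len(self.features)})"
            )
        if not self.classes or len(set(self.classes)) != len(self.classes):
            raise ValueError("type vocabulary must be non-empty and unique")

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights.T + self.intercepts[None, :]

    def save(self, path: str | Path) -> None:
        payload = {
            "scheme": self.scheme,
            "normalization": self.normalization,
            "l2_strength": self.l2_strength,
            "converged": self.converged,
            "classes": list(self.classes),
            "features": list(self.features),
            "intercepts": self.intercepts.tolist(),
            "weights": self.weights.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(payload["weights"], dtype=float),
            intercepts=np.asarray(payload["intercepts"], dtype=float),
            features=tuple(payload["features"]),
            classes=tuple(payload["classes"]),
            l2_strength=float(payload["l2_strength"]),
            scheme=payload["scheme"],
            normalization=payload["normalization"],
            converged=bool(payload["converged"]),
        )


def fit_classifier(
    ref_norm: ad.AnnData,
    labels: Sequence[str] | pd.Series,
    features: FeatureSet,
    l2_strength: float = 1.0,
    seed: int = 0,
    scheme: str = "one-vs-rest",
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> ClassifierModel:
    """Fit one L2 logistic model per reference type (one-vs-rest).

    ``l2_strength`` is the L2 penalty weight (sklearn's C = 1 /
    l2_strength).  No feature scaling is applied beyond the log-library
    normalization of the inputs.
    """
    if l2_strength <= 0:
        raise ValueError("l2_strength must be > 0")
    y = np.asarray(labels, dtype=object)
    if len(y) != ref_norm.n_obs:
        raise ValueError("labels length does not match reference cells")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 reference types")
    small = classes[counts < 2]
    if small.size:
        raise ValueError(f"reference types with < 2 cells: {list(small)}")
    genes = list(features)
    X = _dense(ref_norm[:, genes].X)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in training matrix")

    classes = tuple(str(c) for c in classes)
    converged = True
    if scheme == "one-vs-rest":
        W = np.empty((len(classes), len(genes)))
        b = np.empty(len(classes))
        for i, c in enumerate(classes):
            clf = LogisticRegression(
                penalty="l2",
                C=1.0 / l2_strength,
                solver="lbfgs",
                tol=tol,
                max_iter=max_iter,
                random_state=seed,
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                clf.fit(X, (y == c).astype(int))
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                converged = False
                warnings.warn(
                    f"one-vs-rest fit for type {c!r} hit max_iter={max_iter}",
                    stacklevel=2,
                )
            W[i] = clf.coef_[0]
            b[i] = clf.intercept_[0]
    elif scheme == "multinomial":
        clf = LogisticRegression(
            penalty="l2",
            C=1.0 / l2_strength,
            solver="lbfgs",
            tol=tol,
            max_iter=max_iter,
            random_state=seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(X, y.astype(str))
        converged = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
        order = [list(clf.classes_).index(c) for c in classes]
        W = clf.coef_[order]
        b = clf.intercept_[order]
    else:
        raise ValueError(f"unknown scheme: {scheme!r}")

    return ClassifierModel(
        weights=W,
        intercepts=b,
        features=tuple(genes),
        classes=classes,
        l2_strength=l2_strength,
        scheme=scheme,
        converged=converged,
    )


def predict_probabilities(model: ClassifierModel, query_norm: ad.AnnData) -> pd.DataFrame:
    """Score query cells against every reference type.

    One-vs-rest sigmoid scores renormalized to sum to one per cell
    (softmax for a multinomial model); rows lie on the probability
    simplex.  Returns cells x types with cell ids as index.
    """
    missing = [g for g in model.features if g not in query_norm.var_names]
    if missing:
        raise ValueError(
            f"{len(missing)} model features missing from query (e.g. {missing[:5]}); "
            "re-run feature selection on the shared gene space"
        )
    if query_norm.n_obs == 0:
        return pd.DataFrame(
            np.empty((0, len(model.classes))), columns=list(model.classes)
        )
    X = _dense(query_norm[:, list(model.features)].X)
    scores = model.decision_scores(X)
    if model.scheme == "multinomial":
        probs = softmax(scores, axis=1)
    else:
        s = expit(scores)
        probs = s / s.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        probs, index=list(query_norm.obs_names), columns=list(model.classes)
    )


@dataclass
class ClusterSimilarity:
    """Per-cluster mean probabilities and similarity-band summary.

    ``summary`` columns: cluster, n_cells, assigned_type, similarity
    (mean probability of the assigned type), band (below / moderate /
    high), frac_high (fraction of member cells with per-cell assigned-
    type probability >= the high threshold).
    """

    summary: pd.DataFrame
    mean_probs: pd.DataFrame
    high_threshold: float = HIGH_BAND
    show_threshold: float = SHOW_BAND

    def shown(self) -> pd.DataFrame:
        """Clusters above the show threshold, as plotted in the study-style dot plot."""
        return self.summary[self.summary["band"] != "below"].reset_index(drop=True)


def _band(score: float, show: float, high: float) -> str:
    if score >= high:
        return "high"
    if score >= show:
        return "moderate"
    return "below"


def score_clusters(
    probs: pd.DataFrame,
    partition: ClusterPartition | np.ndarray,
    high_threshold: float = HIGH_BAND,
    show_threshold: float = SHOW_BAND,
) -> ClusterSimilarity:
    """Summarize per-cluster similarity to the reference types.

    Each cluster is assigned the type with the highest mean probability;
    its similarity score is that mean, banded moderate [show, high) or
    high [high, 1].
    """
    labels = partition.labels if isinstance(partition, ClusterPartition) else np.asarray(partition)
    if len(labels) != len(probs):
        raise ValueError("partition not aligned with probability rows")
    if not 0 <= show_threshold <= high_threshold <= 1:
        raise ValueError("need 0 <= show_threshold <= high_threshold <= 1")
    mean_probs = probs.groupby(labels).mean()
    mean_probs.index.name = "cluster"
    rows = []
    for cluster, mrow in mean_probs.iterrows():
        assigned = mrow.idxmax()
        similarity = float(mrow[assigned])
        members = probs.loc[labels == cluster, assigned]
        rows.append(
            {
                "cluster": cluster,
                "n_cells": int((labels == cluster).sum()),
                "assigned_type": assigned,
                "similarity": similarity,
                "band": _band(similarity, show_threshold, high_threshold),
                "frac_high": float((members >= high_threshold).mean()),
            }
        )
    return ClusterSimilarity(
        summary=pd.DataFrame(rows),
        mean_probs=mean_probs,
        high_threshold=high_threshold,
        show_threshold=show_threshold,
    )


@dataclass
class WheelLayout:
    """Reference types on the unit circle; cells as convex combinations."""

    vertex_order: tuple[str, ...]
    vertices: pd.DataFrame  # index type, columns x, y
    cells: pd.DataFrame  # index cell id, columns x, y

    def vertex(self, type_name: str) -> np.ndarray:
        return self.vertices.loc[type_name, ["x", "y"]].to_numpy(dtype=float)


def wheel_coordinates(
    probs: pd.DataFrame, vertex_order: Sequence[str] | None = None
) -> WheelLayout:
    """Project probability rows into the reference polygon.

    Vertex j of the K-gon sits at angle 2*pi*j/K on the unit circle, in
    the given order (default: the probability matrix's column order);
    each cell lands at sum_j p_j * vertex_j.
    """
    types = list(probs.columns)
    order = list(vertex_order) if vertex_order is not None else types
    if sorted(order) != sorted(types):
        raise ValueError("vertex_order must be a permutation of the type vocabulary")
    K = len(order)
    angles = 2.0 * np.pi * np.arange(K) / K
    verts = np.column_stack([np.cos(angles), np.sin(angles)])
    vertices = pd.DataFrame(verts, index=order, columns=["x", "y"])
    P = probs[order].to_numpy(dtype=float)
    cells = pd.DataFrame(P @ verts, index=probs.index, columns=["x", "y"])
    return WheelLayout(vertex_order=tuple(order), vertices=vertices, cells=cells)


def top_coefficient_genes(model: ClassifierModel, type_name: str, k: int = 20) -> list[str]:
    """Genes with the highest positive logistic coefficients for a type
    (the panel construction behind the study-style heatmaps)."""
    if type_name not in model.classes:
        raise ValueError(f"unknown type: {type_name!r}")
    row = model.weights[model.classes.index(type_name)]
    order = np.lexsort((np.arange(len(row)), -row))[:k]
    return [model.features[i] for i in order if row[i] > 0]


def plot_wheel(
    layout: WheelLayout,
    path: str | Path,
    color_by: pd.Series | None = None,
    title: str | None = None,
) -> None:
    """Render the wheel plot (polygon of reference types, cells as dots)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axis = plt.subplots(figsize=(6, 6))
    poly = layout.vertices[["x", "y"]].to_numpy()
    ring = np.vstack([poly, poly[:1]])
    axis.plot(ring[:, 0], ring[:, 1], color="0.6", lw=1)
    if color_by is not None:
        cats = pd.Categorical(np.asarray(color_by))
        for code in range(len(cats.categories)):
            mask = cats.codes == code
            axis.scatter(
                layout.cells["x"][mask],
                layout.cells["y"][mask],
                s=6,
                alpha=0.6,
                label=str(cats.categories[code]),
            )
        axis.legend(fontsize=7, loc="upper right", frameon=False)
    else:
        axis.scatter(layout.cells["x"], layout.cells["y"], s=6, alpha=0.6)
    for name, row in layout.vertices.iterrows():
        axis.annotate(name, (row["x"] * 1.08, row["y"] * 1.08), ha="center", fontsize=8)
    axis.set_aspect("equal")
    axis.set_axis_off()
    if title:
        axis.set_title(title)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
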