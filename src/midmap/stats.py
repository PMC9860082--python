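"""Gene-panel statistics: permutation test, panel scores, enrichment calls.

The panel statistic is the sum over panel genes of their mean
normalized expression across a cell set.  Its permutation null is built
by shuffling group-membership labels across the pooled cells (the
statistic concerns cell groups, so cells — not genes — are the
exchangeable unit) and the one-sided "greater" p-value uses the add-one
estimator, so p is never zero.

Marker enrichment is a Bayesian call on detection fractions: with a
Jeffreys Beta(1/2, 1/2) prior on each group's detection probability,
the posterior probability that the focal type's detection fraction
exceeds the rest is integrated numerically and thresholded (0.998 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import _dense

__all__ = [
    "PanelScore",
    "PermutationResult",
    "EnrichmentCall",
    "score_gene_panel",
    "permutation_test_panel",
    "marker_enrichment",
    "beta_posterior_greater",
]


@dataclass
class PanelScore:
    """Sum over panel genes of mean normalized expression in a cell set."""

    statistic: float
    panel: tuple[str, ...]
    missing: tuple[str, ...]
    n_cells: int
    cell_set: str = ""


@dataclass
class PermutationResult:
    """One-sided permutation test of a panel score against a null of
    shuffled group membership."""

    observed: float
    null_stats: np.ndarray = field(repr=False)
    n_perm: int
    p_value: float
    seed: int
    alternative: str = "greater"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "observed": self.observed,
                    "p_value": self.p_value,
                    "n_perm": self.n_perm,
                    "seed": self.seed,
                    "alternative": self.alternative,
                }
            ]
        )


@dataclass
class EnrichmentCall:
    """Posterior probability that a gene's detection fraction in the
    focal type exceeds the rest."""

    gene: str
    focal_type: str
    posterior: float
    enriched: bool
    threshold: float
    n_focal: int
    k_focal: int
    n_rest: int
    k_rest: int


def _resolve_cells(adata: ad.AnnData, cells) -> np.ndarray:
    """Cell subset -> integer positions (bool mask, positions, or ids)."""
    arr = np.asarray(cells)
    if arr.dtype == bool:
        if arr.size != adata.n_obs:
            raise ValueError("boolean cell mask has wrong length")
        return np.flatnonzero(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(int)
    pos = adata.obs_names.get_indexer(arr)
    if (pos < 0).any():
        raise ValueError("unknown cell ids in subset")
    return pos


def _panel_columns(adata: ad.AnnData, panel: Sequence[str]) -> tuple[list[str], list[str]]:
    present = [g for g in panel if g in adata.var_names]
    missing = [g for g in panel if g not in adata.var_names]
    return present, missing


def score_gene_panel(norm: ad.AnnData, panel: Sequence[str], cells) -> PanelScore:
    """statistic = sum_g mean_c norm(c, g) over the panel and cell set.

    Panel genes absent from the matrix are dropped and recorded.
    """
    present, missing = _panel_columns(norm, panel)
    if not present:
        raise ValueError("no panel gene present in the matrix")
    if missing:
        import warnings

        warnings.warn(f"panel genes absent from matrix: {missing}", stacklevel=2)
    pos = _resolve_cells(norm, cells)
    if pos.size == 0:
        raise ValueError("cell set is empty")
    X = _dense(norm[pos, present].X)
    stat = float(X.mean(axis=0).sum())
    return PanelScore(
        statistic=stat,
        panel=tuple(present),
        missing=tuple(missing),
        n_cells=int(pos.size),
    )


def permutation_test_panel(
    norm: ad.AnnData,
    panel: Sequence[str],
    focal_cells,
    comparison_cells,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test with H1: the panel's sum of average expression
    is greater in the focal group.

    Group-membership labels are permuted across the pooled cells
    ``n_perm`` times and the statistic recomputed on each permuted
    "focal" set of the original size; p = (1 + #{null >= observed}) /
    (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    focal = _resolve_cells(norm, focal_cells)
    comp = _resolve_cells(norm, comparison_cells)
    if focal.size == 0 or comp.size == 0:
        raise ValueError("both cell groups must be non-empty")
    if np.intersect1d(focal, comp).size:
        raise ValueError("focal and comparison groups overlap")

    present, _ = _panel_columns(norm, panel)
    if not present:
        raise ValueError("no panel gene present in the matrix")
    pooled = np.concatenate([focal, comp])
    # per-cell panel sums: statistic over a set = mean of these / sum over genes
    cell_sums = _dense(norm[pooled, present].X).sum(axis=1)
    n_f = focal.size
    observed = float(cell_sums[:n_f].mean())

    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.broadcast_to(cell_sums, (n_perm, cell_sums.size)).copy(), axis=1
    )
    null_stats = perms[:, :n_f].mean(axis=1)
    p = (1.0 + float((null_stats >= observed).sum())) / (1.0 + n_perm)
    return PermutationResult(
        observed=observed,
        null_stats=null_stats,
        n_perm=n_perm,
        p_value=p,
        seed=seed,
    )


def beta_posterior_greater(
    k1: int, n1: int, k2: int, n2: int, grid: int = 20001
) -> float:
    """P(theta1 > theta2) for independent Beta posteriors with Jeffreys
    priors: theta_i ~ Beta(k_i + 1/2, n_i - k_i + 1/2).

    Integrated as E_{theta1}[F2(theta1)] over a midpoint rule in the
    quantile space of theta1, which stays accurate for posteriors
    concentrated near 0 or 1.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2 and n1 > 0 and n2 > 0):
        raise ValueError("need 0 <= k <= n and n > 0 for both groups")
    b1 = sps.beta(k1 + 0.5, n1 - k1 + 0.5)
    b2 = sps.beta(k2 + 0.5, n2 - k2 + 0.5)
    u = (np.arange(grid) + 0.5) / grid
    return float(b2.cdf(b1.ppf(u)).mean())


def marker_enrichment(
    counts: ad.AnnData,
    labels: Sequence[str] | pd.Series,
    gene: str,
    focal_type: str,
    detection_cutoff: int = 1,
    threshold: float = 0.998,
) -> EnrichmentCall:
    """Call a gene enriched in a focal type when the posterior
    probability that its detection fraction exceeds the rest passes the
    threshold (0.998 by default, i.e. >99.8%)."""
    y = np.asarray(labels, dtype=object)
    if len(y) != counts.n_obs:
        raise ValueError("labels length does not match cells")
    if gene not in counts.var_names:
        raise ValueError(f"gene {gene!r} not in matrix")
    focal_mask = y == focal_type
    n_focal, n_rest = int(focal_mask.sum()), int((~focal_mask).sum())
    if n_focal == 0:
        raise ValueError(f"focal type {focal_type!r} has no cells")
    if n_rest == 0:
        raise ValueError("comparison group has no cells")
    x = _dense(counts[:, [gene]].X).ravel()
    detected = x >= detection_cutoff
    k_focal = int(detected[focal_mask].sum())
    k_rest = int(detected[~focal_mask].sum())
    posterior = beta_posterior_greater(k_focal, n_focal, k_rest, n_rest)
    return EnrichmentCall(
        gene=gene,
        focal_type=focal_type,
        posterior=posterior,
        enriched=posterior > threshold,
        threshold=threshold,
        n_focal=n_focal,
        k_focal=k_focal,
        n_rest=n_rest,
        k_rest=k_rest,
    )
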