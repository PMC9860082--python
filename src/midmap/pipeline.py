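"""End-to-end pipeline driver: QC -> normalize -> cluster -> map -> score
-> wheel -> permutation tests, with a run manifest.

The driver wires the library stages together in the order of the
underlying analysis: query cells are QC-filtered and log-normalized,
clustered on a PCA/kNN/Louvain graph, scored against the reference
atlas by one-vs-rest logistic regression, summarized per cluster with
similarity bands and wheel coordinates, and each assigned reference
type is tested with the gene-panel permutation test (panel = that
type's top positive logistic coefficients).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import build_knn_graph, louvain_cluster, reduce_dimensions, report_composition
from .io import read_counts, read_labels
from .mapping import (
    fit_classifier,
    plot_wheel,
    predict_probabilities,
    score_clusters,
    top_coefficient_genes,
    wheel_coordinates,
)
from .preprocess import QCThresholds, filter_cells, normalize_log_library, select_features
from .stats import permutation_test_panel

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All paths and parameters of one pipeline run."""

    ref_counts: str
    ref_labels: str
    query_counts: str
    outdir: str
    query_metadata: str | None = None
    counts_format: str = "mtx"
    # QC
    min_umis_per_cell: int = 1000
    min_genes_per_cell: int = 500
    min_cells_per_gene: int = 0
    # normalization
    scale_factor: float = 10_000.0
    # features
    feature_mode: str = "intersection"
    n_hvg: int | None = None
    # clustering
    n_components: int = 50
    n_neighbors: int = 15
    resolution: float = 1.0
    # classifier
    l2_strength: float = 1.0
    scheme: str = "one-vs-rest"
    # similarity thresholds
    show_threshold: float = 0.5
    high_threshold: float = 0.8
    # permutation test
    n_perm: int = 1000
    panel_size: int = 20
    make_plots: bool = False
    seed: int = 0

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(
            min_umis_per_cell=self.min_umis_per_cell,
            min_genes_per_cell=self.min_genes_per_cell,
            min_cells_per_gene=self.min_cells_per_gene,
        )

    def validate(self) -> None:
        for name in ("ref_counts", "ref_labels", "query_counts"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise ValueError(f"PipelineConfig.{name}: path does not exist: {p}")
        if self.query_metadata is not None and not Path(self.query_metadata).exists():
            raise ValueError(
                f"PipelineConfig.query_metadata: path does not exist: {self.query_metadata}"
            )
        self.qc_thresholds().validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    version: str
    stages: list[dict] = field(default_factory=list)
    checksums: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "version": self.version,
                    "config": self.config,
                    "stages": self.stages,
                    "checksums": self.checksums,
                },
                indent=1,
            )
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _StageTimer:
    def __init__(self, manifest: RunManifest):
        self.manifest = manifest

    def run(self, name: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # annotate with the failing stage
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        self.manifest.stages.append(
            {"stage": name, "seconds": round(time.perf_counter() - t0, 3)}
        )
        return out


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; write all stage outputs and the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), version=__version__)
    timer = _StageTimer(manifest)
    seed = int(config.seed)

    ref = timer.run("load_reference", lambda: read_counts(config.ref_counts, config.counts_format))
    ref_labels = read_labels(config.ref_labels).reindex(ref.obs_names)
    if ref_labels.isna().any():
        raise ValueError("reference labels missing for some reference cells")
    query = timer.run("load_query", lambda: read_counts(config.query_counts, config.counts_format))
    metadata = None
    if config.query_metadata:
        metadata = pd.read_csv(config.query_metadata, sep="\t", index_col=0, dtype=str)

    def _qc():
        keys = list(metadata.columns) if metadata is not None else None
        if metadata is not None:
            q = query.copy()
            q.obs = q.obs.join(metadata)
        else:
            q = query
        return filter_cells(q, config.qc_thresholds(), group_keys=keys)

    query_f, qc_report = timer.run("qc", _qc)
    qc_report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    if qc_report.group_summary is not None:
        qc_report.group_summary.to_csv(outdir / "qc_groups.tsv", sep="\t", index=False)

    ref_norm = timer.run("normalize_ref", lambda: normalize_log_library(ref, config.scale_factor))
    query_norm = timer.run(
        "normalize_query", lambda: normalize_log_library(query_f, config.scale_factor)
    )

    features = timer.run(
        "select_features",
        lambda: select_features(
            ref_norm.var_names,
            query_norm.var_names,
            mode=config.feature_mode,
            k=config.n_hvg,
            ref_norm=ref_norm,
        ),
    )

    d = min(config.n_components, query_norm.n_obs, len(features))
    emb = timer.run("pca", lambda: reduce_dimensions(query_norm, features, d, seed))
    k = min(config.n_neighbors, query_norm.n_obs - 1)
    graph = timer.run("knn", lambda: build_knn_graph(emb, k))
    partition = timer.run(
        "louvain", lambda: louvain_cluster(graph, config.resolution, seed)
    )
    clusters = partition.to_frame()
    clusters["cell_id"] = list(query_norm.obs_names)
    clusters.to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    model = timer.run(
        "fit_classifier",
        lambda: fit_classifier(
            ref_norm, ref_labels, features, config.l2_strength, seed, config.scheme
        ),
    )
    model.save(outdir / "model.json")
    probs = timer.run("predict", lambda: predict_probabilities(model, query_norm))
    probs.rename_axis("cell_id").to_csv(
        outdir / "probabilities.tsv", sep="\t", float_format="%.10g"
    )

    sim = timer.run(
        "score_clusters",
        lambda: score_clusters(
            probs, partition, config.high_threshold, config.show_threshold
        ),
    )
    sim.summary.to_csv(outdir / "cluster_similarity.tsv", sep="\t", index=False, float_format="%.10g")
    sim.mean_probs.to_csv(outdir / "cluster_mean_probabilities.tsv", sep="\t", float_format="%.10g")

    wheel = timer.run("wheel", lambda: wheel_coordinates(probs))
    wheel.vertices.rename_axis("type").to_csv(outdir / "wheel_vertices.tsv", sep="\t", float_format="%.10g")
    wheel.cells.rename_axis("cell_id").to_csv(outdir / "wheel_cells.tsv", sep="\t", float_format="%.10g")
    if config.make_plots:
        timer.run(
            "wheel_plot",
            lambda: plot_wheel(
                wheel,
                outdir / "wheel.svg",
                color_by=pd.Series(partition.labels, index=wheel.cells.index),
            ),
        )

    def _permutation_tests():
        assigned = probs.idxmax(axis=1).to_numpy()
        rows = []
        tested = sorted(set(sim.shown()["assigned_type"]))
        for t in tested:
            panel = top_coefficient_genes(model, t, config.panel_size)
            focal = np.flatnonzero(assigned == t)
            comp = np.flatnonzero(assigned != t)
            if not panel or focal.size == 0 or comp.size == 0:
                continue
            res = permutation_test_panel(
                query_norm, panel, focal, comp, config.n_perm, seed
            )
            rows.append(
                {
                    "reference_type": t,
                    "panel": ",".join(panel),
                    "n_focal": focal.size,
                    "n_comparison": comp.size,
                    "observed": res.observed,
                    "p_value": res.p_value,
                    "n_perm": res.n_perm,
                    "seed": res.seed,
                }
            )
        return pd.DataFrame(rows)

    perm_df = timer.run("permutation_tests", _permutation_tests)
    perm_df.to_csv(outdir / "permutation_tests.tsv", sep="\t", index=False, float_format="%.10g")

    if metadata is not None:
        for col in metadata.columns:
            comp = report_composition(partition, query_norm.obs[col])
            comp.proportions.to_csv(
                outdir / f"composition_{col}.tsv", sep="\t", float_format="%.10g"
            )

    config.to_yaml(outdir / "config.yaml")
    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest.checksums[f.name] = _sha256(f)
    manifest.save(outdir / "manifest.json")
    return manifest
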