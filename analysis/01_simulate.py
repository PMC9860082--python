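"""Generate the synthetic study data: a 10-type midbrain-style
reference atlas and a query "differentiation" dataset with known
ground truth.

The query emulates a time course: day-16 cells are floor-plate/midline
progenitors (including a transitional cluster mixing ProgM and
ProgFPM 50/50), day-21 adds neuroblasts, and day-28 adds neurons
(DA0 and OMTN) plus a small off-target serotonergic fraction.  Two
hESC lines (H9, HS980) contribute alternating cells, HS980 with a
modestly deeper library, so downstream composition checks have a real
signal to chase.
"""

import numpy as np
import pandas as pd

import midmap as mm
from common import DATA, RESULTS, SEED, ensure_dirs

ensure_dirs()

atlas_spec = mm.AtlasSpec(
    n_types=10, n_cells_per_type=200, n_genes=2000, n_markers_per_type=30,
    marker_log2fc=3.0, seed=SEED,
)
atlas, truth = mm.generate_atlas(atlas_spec)
names = truth.type_names  # Rgl1 Rgl3 ProgM ProgFPM ProgFPL NProg NbM NbML1 DA0 DA1
K = len(names)
idx = {n: i for i, n in enumerate(names)}

blocks = [
    # (n_cells, weights, timepoint)
    (150, mm.one_hot_weights(150, K, idx["ProgFPM"]), "d16"),
    (150, mm.one_hot_weights(150, K, idx["ProgM"]), "d16"),
    (100, mm.mixed_weights(100, K, idx["ProgM"], idx["ProgFPM"]), "d16"),
    (150, mm.one_hot_weights(150, K, idx["NProg"]), "d21"),
    (150, mm.one_hot_weights(150, K, idx["NbM"]), "d21"),
    (200, mm.one_hot_weights(200, K, idx["DA0"]), "d28"),
    (150, mm.one_hot_weights(150, K, idx["NbML1"]), "d28"),
    (50, mm.one_hot_weights(50, K, idx["DA1"]), "d28"),
]
w = np.vstack([b[1] for b in blocks])
timepoints = sum(([b[2]] * b[0] for b in blocks), [])
n = len(timepoints)
lines = ["H9", "HS980"] * (n // 2)

query_spec = mm.QuerySpec(
    program_weights=w,
    timepoint_labels=timepoints,
    line_labels=lines,
    line_libsize_log_shift={"HS980": 0.25},
    seed=SEED + 1,
)
query, qtruth = mm.generate_query(truth, query_spec)

mm.write_counts(atlas, DATA / "reference")
mm.write_labels(atlas.obs["cell_type"].astype(str), DATA / "reference_labels.tsv", "cell_type")
mm.write_counts(query, DATA / "query")
query.obs[["timepoint", "line", "true_type"]].rename_axis("cell_id").to_csv(
    DATA / "query_metadata.tsv", sep="\t"
)

summary = (
    query.obs.groupby(["timepoint", "true_type"], observed=True)
    .size()
    .rename("n_cells")
    .reset_index()
)
summary.to_csv(RESULTS / "simulation_design.tsv", sep="\t", index=False)

print(f"reference atlas: {atlas.shape[0]} cells x {atlas.shape[1]} genes, {K} types")
print(f"query: {query.shape[0]} cells over {sorted(set(timepoints))}, lines H9/HS980")
print("design written to results/simulation_design.tsv; data under scratch/data/")
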