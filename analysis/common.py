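"""Shared paths and loaders for the numbered analysis scripts.

Large intermediates (count matrices, per-cell tables, fitted models)
live under scratch/; only small summary tables are written to results/.
Scripts are meant to be run in order from the repository root:

    python analysis/01_simulate.py
    python analysis/02_quality_control.py
    ...
"""

from pathlib import Path

import pandas as pd

import midmap as mm

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
OUTPUT = ROOT / "scratch" / "output"
RESULTS = ROOT / "results"
FIGURES = RESULTS / "figures"

SEED = 20260924
QC = mm.QCThresholds(min_umis_per_cell=1000, min_genes_per_cell=200)


def load_reference():
    ref = mm.read_counts(DATA / "reference")
    labels = mm.read_labels(DATA / "reference_labels.tsv")
    return ref, labels.reindex(ref.obs_names)


def load_query():
    q = mm.read_counts(DATA / "query")
    meta = pd.read_csv(DATA / "query_metadata.tsv", sep="\t", index_col=0, dtype=str)
    q.obs = q.obs.join(meta)
    return q


def normalized_query():
    """QC-filtered, log-library-normalized query (recomputed on load)."""
    q = load_query()
    qf, report = mm.filter_cells(q, QC, group_keys=["timepoint", "line"])
    return mm.normalize_log_library(qf), report


def ensure_dirs():
    for d in (DATA, OUTPUT, RESULTS, FIGURES):
        d.mkdir(parents=True, exist_ok=True)
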