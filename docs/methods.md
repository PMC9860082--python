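# Methods

`midmap` scores how closely in-vitro (hESC-derived) cells resemble the
cell types of an endogenous human ventral-midbrain reference atlas.
This note records the models, conventions and numerical choices behind
each stage, and what the synthetic benchmark does and does not show.

## Synthetic data generator

The controlled-access nature of real differentiation datasets makes a
generative stand-in necessary for testing.  The generator produces:

- **A labeled reference atlas.** Each gene g gets a lognormal baseline
  propensity `lambda_g ~ LogNormal(mu=0, sigma=1)`.  Each of K types
  owns a disjoint set of marker genes (30 per type by default) whose
  propensity is multiplied by `2**marker_log2fc` (default log2FC = 3);
  the type's *program* is the propensity vector renormalized to sum
  to 1.  A cell of type t with library size
  `L ~ LogNormal(ln 10000, 0.3)` has counts
  `x_g ~ NB(mean = L * p_tg, size = 2)` (size = inverse-overdispersion;
  variance = mu + mu^2/size).  This is the standard overdispersed UMI
  noise model; the expression model of the real reference atlas is not
  publicly described, so the NB/lognormal choice is the package's own.
- **Query cells as convex mixtures.** A query cell carries a weight
  vector w on the K-type simplex and its expected program is
  `sum_t w_t * p_t`.  One-hot rows model pure identities; 50/50 rows
  model transitional progenitors that partially share two identities.
  Mixtures are of mean programs, *not* doublet count sums — the target
  is biological intermediacy, not technical artifacts.
- The default library-size scale (e^mu ≈ 10,000 UMIs) sits inside the
  range reported for real differentiation time courses (mean UMIs
  roughly 7,000–15,000); an optional per-line log-shift emulates two
  hESC lines sequenced at different depths.

What the generator does **not** emulate: ambient RNA, doublets,
batch/chemistry effects beyond the per-line depth shift, gene–gene
correlation beyond the marker programs, and zero-inflation beyond what
NB sampling produces.  Passing tests therefore demonstrate correctness
of the algorithms under a clean generative model, not performance on
real data.

## QC and normalization

Cells are filtered on total UMIs and detected genes (defaults 1000 /
500 — configuration values, not measured thresholds), optionally on
mitochondrial fraction; genes on the number of retained cells
expressing them.  Cells are filtered first, genes second, and the two
passes are iterated to a fixed point so that filtering is idempotent.

Normalization is log-library-size:
`y_cg = ln(1 + s * x_cg / L_c)` with `s = 10,000` and natural log.
The published analyses state only "log-library size normalized"; base
and scale are fixed here as one documented convention.  The transform
is exactly zero-preserving and strictly monotone within a cell, and is
tested against a naive double-loop recomputation at 1e-12.

## Clustering

PCA (exact SVD) on the centered feature submatrix, with each
component's sign fixed so its largest-magnitude loading is positive;
d = 50 components by default, capped by the data.  An exact kNN graph
(k = 15, Euclidean metric, ties broken by lowest cell index) is
mutualized into an undirected unit-weight graph, and Louvain
modularity optimization (networkx implementation, seeded) partitions
it at resolution 1.0.  Communities are relabeled 0..C-1 by their
lowest member index; an edgeless graph yields singletons with
modularity 0.  Louvain rather than Leiden is the deliberate default;
the parameters are package defaults since the original Cytograph
settings are not published.

## Reference mapping

One binary L2-regularized logistic regression per reference type
(one-vs-rest), fit with lbfgs to tolerance 1e-6 on the shared
(reference ∩ query) gene space of log-normalized expression, with no
further feature scaling; `l2_strength` = 1.0 (sklearn C = 1).  At
prediction, the per-type sigmoid scores are renormalized to sum to 1
per cell.  The OvR-plus-renormalization convention reads the per-type
scores as independent class memberships, matching how per-reference-
type similarity scores are usually reported; a multinomial softmax
variant is available behind `scheme="multinomial"`.

Per-cluster similarity: mean probability per type, assignment by
argmax, similarity = mean probability of the assigned type.  Bands are
half-open — moderate [0.5, 0.8), high [0.8, 1.0] — so that every score
has exactly one band, matching scores printed as "0.5–0.79" and
"0.8–1.0".  The per-cell "highly similar" cutoff mirrors the
cluster-level high band (0.8).

The wheel (polygon) plot places the K reference types at angles
2*pi*j/K on the unit circle (vertex order configurable; default is the
vocabulary order) and each cell at its probability-weighted average of
the vertices.  One-hot rows land exactly on vertices, uniform rows at
the origin, and every cell stays inside the polygon's convex hull —
these identities are tested to 1e-12.

## Panel statistics

- **Panel score:** sum over panel genes of the gene's mean normalized
  expression across a cell set.
- **Permutation test:** H1 is that the panel score is greater in the
  focal group.  Group-membership labels are permuted across the pooled
  cells (cells, not genes, are the exchangeable unit — the hypothesis
  concerns cell groups; this is an interpretation, documented as such),
  1,000 permutations by default, with the add-one estimator
  `p = (1 + #{null >= obs}) / (1 + n_perm)`, so p >= 1/(n_perm+1).
- **Marker enrichment:** detection fractions (count >= cutoff, default
  1 UMI) in the focal type vs the rest are given independent Beta
  posteriors under Jeffreys priors Beta(1/2, 1/2);
  `P(theta_focal > theta_rest)` is computed by a midpoint rule over the
  focal posterior's quantile space (20,001 nodes), which stays accurate
  when posteriors concentrate near 0 or 1; the call threshold is a
  posterior > 0.998.  This Beta-posterior construction is a documented
  stand-in for trinarization-style enrichment flags.  With very deep
  libraries, detection at 1 UMI saturates; raising the cutoff (the
  analysis drivers use 10) turns the call into "robustly expressed".

## Pipeline and determinism

`run_pipeline` chains QC → normalize → feature selection → PCA/kNN/
Louvain → classifier → cluster scoring → wheel → per-type permutation
tests (panel = the type's top positive coefficients), writes every
stage output as TSV plus a JSON manifest with per-file SHA-256
checksums, and is byte-deterministic given a config and seed.  Stage
errors abort with the stage name attached.

## Problem sizes

The bundled analyses and checks run on a 10-type atlas (200 cells/type,
2,000 genes) and a 1,100-cell query; calibration studies use 1,000 null
simulations at 199 permutations each.  These sizes make every property
measurable with comfortable margins while keeping a full run of the
analysis under a minute on one CPU.

## Known limitations

- No batch correction between reference and query (or between two
  reference sources); mapping quality on real cross-chemistry data
  will be worse than the clean-simulation benchmarks.
- No rejection class: a cell unlike every reference type still
  receives a renormalized probability vector.
- The permutation unit and the enrichment construction are documented
  interpretations where the original descriptions are underspecified.
- Exact QC thresholds of the original analyses are not public; the
  defaults here are package conventions.
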