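# Methods

## Setting and model

Two gene-by-cell count matrices are observed: a reference with per-cell
type labels and an unlabeled query. Cell types shared between the two may
be measured under different technical conditions (batch effects), and the
query may contain types absent from the reference. The goal is open-set
annotation: label every query cell with a reference type, a novel-type ID,
or `unassigned`.

The pipeline builds one joint embedding of all cells and fuses two signals
computed in it: a supervised multiclass classifier (trained on reference
cells only) and an unsupervised density clustering (computed on all cells).
The fusion rule is per cell: trust the classifier when its maximum class
probability clears a data-adaptive threshold, otherwise fall back to the
cell's density cluster, which — if it is a cluster the reference does not
populate — becomes a novel-type label.

## Preprocessing

* **Gene space.** Reference and query are restricted to the sorted
  intersection of their gene IDs; fewer than `min_shared_genes` (default
  200) shared genes is an error, since downstream embeddings would be
  meaningless.
* **Normalization.** Counts are scaled per cell to `scale_factor` = 10,000
  and log1p-transformed — the de-facto standard for UMI data. Zero-count
  cells are dropped with a warning.
* **HVG selection** (default `n_hvg` = 2,000, on the *combined* data so
  query-only populations contribute variance): per-gene standardized
  variance under a mean–variance trend. The trend is a degree-2 polynomial
  of log10(variance) on log10(mean) fit on the raw-count scale; per-gene
  z-scores against the fitted SD are clipped at √N before the variance of
  the clipped scores is taken. Constant genes score zero and are never
  selected. Ties break by gene ID so the selection is reproducible.
* **PCA** (default `n_pcs` = 50): truncated SVD of the per-gene z-scored
  (clipped at ±10) HVG matrix. Component signs are fixed by making the
  largest-magnitude loading positive; with a seeded start vector the
  embedding is bit-reproducible. Requests above the matrix rank are reduced
  with a warning.

## Embedding and clustering

* **Batch correction** operates in PC space on exactly the two batches
  "reference" and "query". The default backend (`center_fallback`) centers
  each batch's PC columns, which removes any constant batch offset exactly
  and keeps the package dependency-light; an adapter to the Harmony
  iterative soft-clustering correction activates when `harmonypy` is
  importable. Centering is symmetric under batch relabeling and is the
  right model for the simulator's multiplicative (≈ additive in log space)
  batch effect; real data with composition imbalance between batches will
  benefit from the Harmony backend (see Limitations).
* **UMAP** (defaults `n_neighbors` = 15, `min_dist` = 0.1, Euclidean):
  2-D embedding of the corrected PCs. A fixed `random_state` forces the
  single-threaded exact path, making runs bit-reproducible.
* **DBSCAN** (defaults `eps` = 0.5, `min_samples` = 5, applied to raw UMAP
  coordinates): standard density semantics; unreachable cells keep the
  noise label −1. **`eps` is scale-sensitive** because UMAP coordinate
  ranges vary with data size and parameters; both knobs are first-class
  configuration. Cluster IDs are renumbered by decreasing size (ties by
  smallest member index) so they are stable across runs. A naive O(n²)
  implementation with identical semantics ships as a test oracle and
  refuses inputs above 5,000 points.

## Multi-resolution features

The classifier input concatenates, per cell: 50 corrected PCs (broad
transcriptional programs), 2 UMAP coordinates (manifold neighborhood), and
1 integer cluster ID (unsupervised grouping; −1 = noise) — 53 columns under
defaults. The numeric blocks are passed through unchanged: gradient-boosted
trees are invariant to per-feature monotone rescaling, so no
re-standardization across resolutions is needed.

## Classifier

A LightGBM gradient-boosted tree multiclass model (softmax objective,
default 500 max iterations, depth 6, learning rate 0.1, fixed seed, single
thread) over the 53-column schema, with three design elements that exist to
keep the *probability output* meaningful, because the downstream decision
rule consumes probabilities, not just argmax labels:

1. **Cluster target statistics.** The categorical cluster column is encoded
   as smoothed per-class target statistics: for cluster *c* and class *k*,
   (n<sub>c,k</sub> + a·prior<sub>k</sub>) / (n<sub>c</sub> + a) with
   pseudo-count a = 10. Training rows are encoded out-of-fold (5 folds) so
   no row's statistic includes its own label. A category never seen in
   training maps to the prior itself — the behavior that makes open-set
   detection possible.
2. **Prior anchoring.** Boosting starts from init score = log(target
   statistic); the trees fit residual corrections using all features.
3. **Early stopping.** 20% of the reference (stratified, seeded) is held
   out and boosting stops when per-round validation log-loss gains fall
   below 10⁻³. Without this, hundreds of residual rounds saturate every
   probability at ~1 and the confidence signal degenerates. For very small
   or unstratifiable references the model falls back to a plain fit.
4. **Support-conditional corrections.** Tree corrections are validated only
   on reference-populated clusters, so they are applied only to cells whose
   cluster category has reference support. A cell in a query-only cluster
   keeps the prior class distribution — maximum probability ≈ 1/K — which
   is precisely the low-confidence anchor the decision rule expects.
   Without this rule, tree ensembles extrapolate a confident (and
   unfalsifiable) label onto out-of-distribution cells: every leaf region
   extends to infinity and novel populations inherit whichever training
   class shares their half-spaces. DBSCAN noise (−1) is an ordinary
   category: if reference noise cells exist it gets its own statistic,
   otherwise it maps to the prior.

Feature importance is reported as normalized gain, with the gains of the
internal per-class cluster statistics — plus the log-loss reduction of the
prior-anchored init over the class prior — credited to the single cluster
feature, so the report stays in the 53-feature vocabulary.

## Confidence threshold and label fusion

Max-probabilities of **all** cells (reference and query pooled with equal
weight) are sorted in decreasing order; the threshold is the midpoint of
the largest consecutive drop, ties broken toward the higher-probability
pair, clipped into [1/K, 1). If no drop exceeds `min_gap` (10⁻⁶) the
distribution is flat and the threshold falls back to 1/K — making every
cell confident, i.e. pure supervised behavior when there is no evidence of
an unconfident subpopulation. Cells exactly at the threshold count as
confident (`confident_op` = "ge", configurable).

The per-cell rule is applied literally: a low-confidence cell in *any*
cluster receives that cluster's novel ID, even if the cluster is dominated
by confidently annotated known-type cells. This reproduces the method's
characteristic error modes — known-type subpopulations can surface as
"novel" (arguably a feature: subtype discovery), and one-or-two-cell noise
clusters warrant skepticism.

## Synthetic data generator

Emulates exactly the structure the pipeline's claims depend on:

* gene baseline means ~ LogNormal(−1, 1) (most genes low, a long tail);
* disjoint 50-gene marker blocks per type, multiplied by 2^`marker_lfc`
  (default 16×) within the type;
* a per-gene multiplicative batch factor ~ LogNormal(0, 0.3) applied to
  query cells only;
* per-cell library factors ~ LogNormal(0, 0.3);
* counts ~ NB(mean μ, variance μ + μ²/θ), θ = 10.

The default benchmark ("simbench-1"): 2,000 genes; five known types with
300 reference + 300 query cells each; two query-only novel types of 150 and
20 cells; seed 20240101 — sized so the full pipeline runs in about a minute
on one CPU. The 20-cell type probes the rare-population limit: DBSCAN with
`min_samples` = 5 can still form a cluster from ~20 dense cells.

What it does **not** emulate: gene–gene correlation within programs,
continuous trajectories or partially overlapping types, doublets, ambient
RNA, or dropout beyond NB sampling. Consequently the synthetic types are
well-separated blobs, and passing benchmarks demonstrates the machinery —
correct plumbing, calibrated confidence, threshold placement, distinct
novel IDs — rather than performance on transcriptionally adjacent real
populations (where novel subtypes of referenced lineages will often
collapse into their parent label).

## Numerical and procedural choices

* Two reference types are withheld in the hold-out experiment: the last two
  known types in sorted-name order (a deterministic, composition-neutral
  choice).
* The threshold search uses the full probability multiset, not unique
  values; duplicate-heavy vectors have zero internal gaps either way.
* Determinism: one seed drives the SVD start vector, UMAP, fold splits and
  LightGBM; all stages run single-threaded by default, so identical inputs
  and seeds reproduce the annotation CSV byte for byte. The reproducibility
  check in the test suite uses a reduced-size simulation (600 genes, three
  known types, one novel type) — determinism does not depend on problem
  size.
* Evaluation: confusion-matrix columns are aligned to truth rows by a
  Hungarian assignment maximizing matched cell count; "sensitivity" and
  "specificity" in per-class reports are implemented as recall and
  precision (matched/row-total and matched/column-total), the only reading
  consistent with worked examples like 441/444 = 99.3% and 441/442 = 99.8%.

## Limitations

* Per-batch centering cannot correct composition-dependent distortions;
  with strongly imbalanced shared types between reference and query, use
  the Harmony backend.
* DBSCAN's `eps` on UMAP coordinates has no universal default; badly scaled
  values either merge everything (one cluster) or fragment everything
  (all noise). Inspect the logged cluster count.
* Novel types transcriptionally close to a referenced lineage are
  frequently absorbed into it (the classifier is confident, so the cluster
  signal never applies).
* Populations below ~`min_samples` cells cannot form their own cluster and
  will surface as noise (`unassigned`) at best.
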