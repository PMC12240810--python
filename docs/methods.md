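# Methods

This note documents the models implemented in `loki-st`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do
and do not demonstrate.

## Gene sentences and preprocessing

An expression profile is represented as the ordered list of its top-k
expressed gene symbols (k = 50 by default), ranked by value, descending.
Ties break by ascending input gene order, which makes sentence construction
fully deterministic; zero-valued genes are never emitted, so sentences may
be shorter than k. Because ranking is invariant under any strictly monotone
per-profile transform, raw and normalized counts yield identical sentences;
normalization (library-size scaling to 10,000 followed by log1p — the
standard single-cell protocol) matters only for exported matrices and for
expression *prediction* targets. Profiles stored in TPM/FPKM units cannot
be re-normalized to count space and pass through untouched.

Quality control keeps spots expressing strictly more than 200 genes ("over
200" read as a strict inequality, configurable). After identifier-to-symbol
mapping, rows sharing a symbol are **summed** — this conserves per-spot
library size over the mappable genes; the alternative (keeping the
highest-count row) discards counts. Housekeeping-gene removal accepts any
user-supplied list; no specific source list is bundled.

## Reference encoders

The shipped encoders are deterministic stand-ins for a trained dual
encoder, built so every downstream algorithm is exercised end to end:

* **Text**: each gene symbol gets a fixed Gaussian direction (variance
  1/d, d = 768) derived from a stable blake2 hash of the symbol mixed with
  the seed. A sentence embeds as Σᵣ v(gᵣ)/log₂(r+1) over its first
  `max_genes` symbols — order-sensitive by construction, so reversing a
  sentence changes its embedding.
* **Image**: a seeded Gaussian linear projection of the feature vector
  (variance 1/f per input, preserving scale); raster patches are
  mean-pooled per channel first. Zero features map to the zero embedding.

Both are bit-reproducible given (input, seed, embed_dim). They are *not*
reproductions of any trained transformer; in particular the two modalities'
raw spaces are unrelated random projections, so **zero-shot cross-modal
similarity carries no signal**. Cross-modal structure is created by the
adapter heads (below), mirroring the per-task fine-tuning step of the full
platform. The 76-token encoder input limit is modeled as truncation at
`max_genes` = 50 symbols; a sub-word token budget is not emulated.

## Contrastive objective and adapter fine-tuning

The loss is the symmetric InfoNCE over a batch of N pairs with temperature
σ (default 0.07, the common contrastive default — configurable, and treated
as fixed rather than learnable). Embeddings are L2-normalized inside the
loss and all similarity computations; raw encoder outputs are stored
unnormalized.

Fine-tuning trains two linear adapter heads (identity-initialized, d×d) on
top of the frozen reference embeddings by minibatch gradient descent
(batch 64, learning rate 0.5) on the InfoNCE loss; gradients are derived in
closed form and verified against finite differences in the test suite. Ten
epochs — the platform's standard fine-tuning budget — suffice to align the
two reference spaces on a 200-spot cohort (mean paired cosine rises from
≈ 0 to ≈ 0.9). The per-epoch loss trace records the full-batch loss before
any step and after each epoch.

## Alignment (embedding-augmented CPD)

Spots are 4-D points: two spatial coordinates plus the first two principal
components of their embeddings. The PCA basis is fitted on the **pooled**
embeddings of both sections and the feature scores are standardized with
pooled statistics — a per-section basis would make the feature columns
incomparable across sections and destroy the cross-section attraction the
augmentation exists for. Spatial and feature columns are z-scored
independently; `feature_scale` (default 1.0) balances the modalities.
Embeddings with fewer than two informative principal components fall back
to 1 or 0 feature columns with a warning.

CPD specifics:

* σ² initializes to the mean squared distance over all point pairs and all
  D dimensions, floored at 1e-12.
* The E-step is computed in log space (log-sum-exp); with outlier weight
  w = 0 the posterior columns sum to exactly 1. Defaults β = 2, λ = 2,
  w = 0 are the classical CPD choices on standardized coordinates.
* The M-step solves (G + λσ² d(P1)⁻¹)W = d(P1)⁻¹PX − Y for the **spatial
  columns only**; the feature columns of W are identically zero, so the
  embedding coordinates are never deformed. E-step distances and the σ²
  update use all D dimensions. A singular system falls back to a logged
  ridge jitter. A printed constraint 0 ≤ W ≤ 1 on the transform matrix is
  dimensionally inconsistent for a displacement-coefficient matrix and is
  off by default (`clip_w` enables it).
* Convergence: relative σ² change < 1e-5 or 100 iterations; non-convergence
  returns a result flagged `converged=False`.
* The rigid projection is an orthogonal Procrustes fit (rotation with
  det +1, plus translation) from the source spots' original coordinates to
  the nonrigid fit, computed in the target's original units. It is the
  default output — an exact isometry of the source — with the raw nonrigid
  fit also returned.

**Recovery scoring.** Per-spot coordinate jitter is not invertible by any
rigid map: under the low-noise preset (jitter sd = 0.25 spacing) the
per-spot residual floor is 0.25·√(π/2) ≈ 0.31 spacing no matter how good
the registration is. Recovery is therefore scored as *transform* recovery:
the estimated rigid map applied to the noise-free perturbed coordinates,
compared with the true coordinates. The augmented-vs-spatial-only
comparison runs at 30° rotation: at small rotations spatial-only CPD
already recovers the transform and both arms tie at the estimation floor,
while at 30° the near-symmetric spot grid makes pure-geometry registration
ambiguous and the embedding features resolve it — the regime in which
embedding augmentation earns its keep. Expression-level evaluation
(`evaluate_alignment`) maps each aligned spot to its nearest target spot
and reports median per-spot Pearson and Kendall-tau correlations over the
most variable shared genes.

## Decomposition

The mapping matrix M (spots × cells or clusters) is parameterized as a
columnwise softmax of an unconstrained matrix, so each cell's column is a
probability distribution over spots at every optimizer step — no
projection needed. Plain gradient descent (lr = 0.1, 1000 epochs, seeded
0.01-scale initialization) minimizes the summed per-embedding-dimension
cosine distance between M S and G, with a uniform density prior (no
per-spot count term). The printed loss writes MᵀS with M spots×cells and
S cells×embeddings, which does not conform; M S is the intended product.
Cluster-level mapping (mean embedding per cluster, sizes recorded)
accelerates large references; fractions weight each cluster column by its
size before row normalization. NMS refinement keeps the per-spot argmax
type at its original value (ties → lowest type index) and is idempotent.

Evaluation follows the per-type reading: each cell type's spot vector is
normalized to a distribution over spots for the JS divergence (base-2
logarithms, forced by the divergence's stated [0,1] range), and SSIM
treats the raw per-type spot vector as a single-window image — spots are
irregular points, not a raster — with C1 = (0.01 L)², C2 = (0.03 L)²,
L the pooled value range floored at 1e-8, and population variances.

## Retrieval and expression prediction

Retrieval ranks a bank by cosine similarity (ties broken by bank insertion
order); a query's ground-truth quantile is its 1-based rank divided by the
bank size, and Recall@K is the fraction of queries at quantile ≤ K. Under
random ranking E[Recall@K] = K, the chance level the benchmarks compare
against.

Prediction is the similarity-weighted average of training expression.
Cosine weights can be negative, and a denominator eroded by sign
cancellation flips or amplifies the prediction arbitrarily (an early
version of the harness produced thousand-fold errors this way); when a
query's weight sum falls below half its positive weight mass, only
strictly positive weights are used, and if none are positive the unweighted
training mean is returned with a warning. With an all-positive similarity
structure the guard never triggers and the printed formula applies
unchanged.

The cross-validation harness fine-tunes adapters on each training split
(10 epochs), selects the validation split's top-expressed genes as the
panel — as in the original protocol, which leaks the validation gene
ranking into evaluation; `panel_from="train"` avoids this — and reports
per-fold MSE (per-spot, averaged) and per-gene Pearson correlation
(median). The headline is the median over folds of the per-fold median
per-gene correlation; per-spot correlations are also emitted. Prediction
operates on log-normalized expression so that library-depth variation does
not dilute per-gene correlations.

## Synthetic cohorts

`simulate_paired_cohort` emulates the paired structure the dual encoder
assumes. Defaults define the benchmark conditions: 200 spots on a unit
grid, 300 genes, K = 4 cell types, 25 boosted marker genes per type over a
shared gamma baseline, per-spot mixtures Dirichlet-distributed around
smooth spatial archetypes (bandwidth 4 grid units, concentration 0.5),
counts negative-binomial (dispersion 10, libraries 2000–4000), and image
features a fixed linear readout of the true mixture plus optional Gaussian
noise (sd 0 by default — the "noiseless coupled" condition). Section
perturbation composes a rigid motion, per-spot Gaussian jitter and
count resampling that conserves per-spot totals; the low/high presets
(10%/40% of counts resampled, jitter 0.25/1.0 × spacing) are documented
constants of this package, not published values. Depth downsampling is
per-count binomial thinning to a target median depth; pseudo-Visium
binning averages member-cell profiles (averaging, not summing) within
spot radius.

What these cohorts do **not** emulate: real H&E texture (features are
abstract linear readouts), segmentation noise, batch effects, spatial
autocorrelation of technical noise, or realistic gene–gene correlation
beyond the mixture structure. Passing benchmarks therefore demonstrates
the correctness and statistical behaviour of the algorithms under their
own model assumptions, not performance on real tissue.

## Problem sizes and runtimes

The shipped benchmarks use 200-spot cohorts, 20 alignment replicates,
4-type decomposition with 50 reference cells per type, a 200-entry
retrieval bank and 10-fold cross-validation; the full acceptance run
completes in about half a minute on one CPU, and the test suite in about
half a minute more. These sizes are desk-scale analogs chosen so every
claim is recomputed from scratch on every run.

## Known limitations

* The reference encoders' inductive bias (bag-of-genes with rank decay) is
  far weaker than a trained transformer's; absolute benchmark numbers are
  not comparable to results obtained with trained weights.
* Alignment is pairwise; multi-slice stacks must be chained by the caller.
  The rigid projection is rotation+translation only — no scaling, no full
  projective homography.
* The decomposition loss is nonconvex; different seeds can reach different
  local optima (columns of M for interchangeable cells may swap). Cluster
  interchangeability is resolved only through the type labels.
* `cosdistance` weighting across embedding dimensions is uniform; no
  per-dimension variance weighting is applied.
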