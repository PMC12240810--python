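# loki-st

A toolkit for joint analysis of spatial transcriptomics (ST) and histology
through a shared embedding space. It is aimed at computational biologists
working with Visium-style spot data who want to align adjacent tissue
sections, annotate tissue regions from bulk RNA-seq or marker genes,
decompose spots into cell types, retrieve transcriptomic profiles from image
queries, and predict spot-level expression from images — all through one
cross-modal representation.

## The model

**Gene sentences.** Every expression profile (spot, cell, or bulk sample) is
reduced to text: its top-k expressed gene symbols (default k = 50), ranked
high to low and joined by spaces, e.g. `SNAP25 ENO2 CKB GRIN2C CAMK4 …`.
Ranking is invariant to any monotone per-profile normalization.

**Dual encoders.** A text encoder maps gene sentences and an image encoder
maps patch feature vectors to a shared d-dimensional space (d = 768). The
package ships deterministic, training-free *reference* encoders — a
rank-weighted bag-of-genes with weights 1/log₂(rank+1) under a seeded random
projection for text, and a seeded linear projection for images. Cross-modal
alignment is produced by linear adapter heads trained with the symmetric
InfoNCE objective

L = −(1/N) Σᵢ [ log( e^{xᵢᵀyᵢ/σ} / Σⱼ e^{xᵢᵀyⱼ/σ} ) + log( e^{yᵢᵀxᵢ/σ} / Σⱼ e^{yᵢᵀxⱼ/σ} ) ],

with L2-normalized embeddings x, y and temperature σ = 0.07.

**Alignment.** Adjacent sections are registered with coherent point drift
(CPD): spots are 4-D points — two spatial coordinates plus the first two
principal components of their embeddings — so transcriptionally similar
regions attract during the E/M iterations. Only the spatial coordinates are
deformed; a final rigid (rotation + translation) projection of the nonrigid
fit is returned by default to suppress distortion.

**Decomposition.** A spots-by-cells probability matrix M (each cell's
column a softmax over spots) is optimized by gradient descent on
Σₖ cosdist((M S)₍:,ₖ₎, G₍:,ₖ₎), mapping reference embeddings S onto target
embeddings G, with a uniform density prior. Per-spot cell-type fractions
follow by label-wise summation; an optional non-maximum-suppression step
keeps only the top type per spot.

**Retrieval and prediction.** Image queries rank a transcriptomic bank by
cosine similarity (scored by Recall@K over bank quantiles), and spot
expression is predicted as the similarity-weighted average
Xᵢ = Σⱼ wᵢⱼXⱼ / Σⱼ wᵢⱼ over training spots, with a 10-fold cross-validation
harness.

**Metrics.** Calinski–Harabasz, Pearson, Kendall tau-b, Jensen–Shannon
divergence (base-2, in [0,1]), single-window SSIM, MSE, weighted F1, and the
cross-method impact score (mean of the SSIM z-score and the sign-inverted
JS z-score).

Seeded synthetic generators (`loki.simdata`) produce paired
expression/image cohorts with known cell-type mixtures, perturbed adjacent
sections with known transforms, depth-downsampled counts and pseudo-Visium
binned single cells, so the whole pipeline is testable without downloads.

## Worked example

Register a perturbed adjacent section back onto its source:

```python
import numpy as np
from loki import simdata, align
from loki.encoder import EncoderConfig, TextEncoder
from loki.sentences import build_corpus

# simulate a 200-spot section and a rotated, noisy adjacent section
cohort = simdata.simulate_paired_cohort(simdata.CohortSpec(seed=0))
section, truth = simdata.perturb_section(
    cohort.spots, simdata.PerturbSpec.low(rotation_deg=30, seed=0)
)

# gene sentences -> text embeddings for both sections
cfg = EncoderConfig(seed=0)
enc = TextEncoder(cfg)
target_embs = enc.encode_many(build_corpus(cohort.spots, deduplicate=False).sentences)
source_embs = enc.encode_many(build_corpus(section, deduplicate=False).sentences)

# embedding-augmented CPD registration with rigid projection
result = align.align_sections(section.coords, cohort.spots.coords,
                              source_embs, target_embs)
residual = np.linalg.norm(result.coordinates - truth["true_coords"], axis=1)
print(f"converged: {result.converged} after {len(result.sigma2_trace) - 1} iterations")
print(f"recovered rotation (deg): "
      f"{np.degrees(np.arctan2(result.rotation[1, 0], result.rotation[0, 0])):.2f}")
print(f"mean residual vs true positions: {residual.mean():.3f} grid units")
```

prints

```
converged: True after 15 iterations
recovered rotation (deg): -30.39
mean residual vs true positions: 0.308 grid units
```

The section was rotated by +30°; the registration recovers the inverse map
(−30.4°), and the residual 0.31 grid units equals the floor set by the
per-spot coordinate jitter of the low-noise preset (sd 0.25 ⇒ expected
displacement 0.25·√(π/2) ≈ 0.31) — i.e. the recoverable transform is fully
recovered.

A `loki` command-line interface exposes the same pipeline
(`loki simulate`, `loki sentences`, `loki encode`, `loki align`,
`loki annotate`, `loki decompose`, `loki retrieve`, `loki predex`,
`loki metrics`); every artifact is written with a JSON manifest recording
inputs, parameters and seed.

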