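"""Dual encoders mapping gene sentences and image features to a shared space.

The contract is the usual contrastive dual-encoder one: a text encoder for
gene sentences and an image encoder for patch feature vectors, both emitting
vectors of a fixed ``embed_dim`` (default 768), trained or fine-tuned with a
symmetric InfoNCE loss so that paired (image, sentence) embeddings are
mutually similar.

The reference encoders implemented here are deterministic and training-free:

* text — each gene symbol is assigned a fixed Gaussian direction derived
  from a stable hash of the symbol and the seed; a sentence embeds as the
  rank-weighted sum of its gene directions with weight ``1/log2(rank+1)``
  (rank 1-based), so order matters and truncation at ``max_genes`` mirrors
  the encoder's input budget.
* image — a seed-fixed Gaussian linear projection of the feature vector
  (raster patches are mean-pooled per channel first).

They are reference implementations of the encoder *contract*, not a
reproduction of any trained transformer.  Cross-modal alignment between the
two reference spaces is produced by the linear adapter heads trained with
:func:`finetune_adapters`, mirroring the per-task fine-tuning step of the
full platform.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .sentences import GeneSentence
from .st_io import InputError

__all__ = [
    "EncoderConfig",
    "TextEncoder",
    "ImageEncoder",
    "AdapterPair",
    "encode_text",
    "encode_image",
    "cosine_similarity",
    "contrastive_loss",
    "contrastive_loss_and_grad",
    "finetune_adapters",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Shared encoder configuration.

    ``temperature`` is the InfoNCE temperature sigma (default 0.07, the
    common contrastive default); ``max_genes`` caps how many leading symbols
    of a sentence the text encoder consumes.
    """

    embed_dim: int = 768
    temperature: float = 0.07
    seed: int = 0
    max_genes: int = 50

    def __post_init__(self) -> None:
        if self.embed_dim < 2:
            raise InputError("embed_dim must be >= 2")
        if self.temperature <= 0:
            raise InputError("temperature must be positive")


def _stable_symbol_hash(symbol: str) -> int:
    digest = hashlib.blake2b(symbol.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2**31)


class TextEncoder:
    """Rank-weighted bag-of-genes reference text encoder (deterministic)."""

    def __init__(self, cfg: EncoderConfig):
        self.cfg = cfg
        self._gene_vectors: dict[str, np.ndarray] = {}

    def _gene_vector(self, symbol: str) -> np.ndarray:
        vec = self._gene_vectors.get(symbol)
        if vec is None:
            seq = np.random.SeedSequence([self.cfg.seed, _stable_symbol_hash(symbol)])
            rng = np.random.default_rng(seq)
            vec = rng.standard_normal(self.cfg.embed_dim) / np.sqrt(self.cfg.embed_dim)
            self._gene_vectors[symbol] = vec
        return vec

    def encode(self, sentence: GeneSentence) -> np.ndarray:
        if len(sentence) == 0:
            raise InputError("cannot encode an empty sentence")
        out = np.zeros(self.cfg.embed_dim)
        for rank, symbol in enumerate(sentence.genes[: self.cfg.max_genes], start=1):
            out += self._gene_vector(symbol) / np.log2(rank + 1)
        return out

    def encode_many(self, sentences) -> np.ndarray:
        return np.stack([self.encode(s) for s in sentences])


class ImageEncoder:
    """Seed-fixed linear projection reference image encoder."""

    def __init__(self, cfg: EncoderConfig):
        self.cfg = cfg
        self._projections: dict[int, np.ndarray] = {}

    def _projection(self, in_dim: int) -> np.ndarray:
        proj = self._projections.get(in_dim)
        if proj is None:
            seq = np.random.SeedSequence([self.cfg.seed, 0x1A6E, in_dim])
            rng = np.random.default_rng(seq)
            proj = rng.standard_normal((in_dim, self.cfg.embed_dim)) / np.sqrt(in_dim)
            self._projections[in_dim] = proj
        return proj

    def encode(self, patch: np.ndarray) -> np.ndarray:
        patch = np.asarray(patch, dtype=float)
        if patch.ndim == 3:  # raster H x W x C -> per-channel mean pool
            patch = patch.mean(axis=(0, 1))
        if patch.ndim != 1:
            raise InputError("image input must be a feature vector or H x W x C raster")
        return patch @ self._projection(patch.size)

    def encode_many(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches, dtype=float)
        if patches.ndim != 2:
            return np.stack([self.encode(p) for p in patches])
        return patches @ self._projection(patches.shape[1])


def encode_text(sentence: GeneSentence, cfg: EncoderConfig) -> np.ndarray:
    return TextEncoder(cfg).encode(sentence)


def encode_image(patch: np.ndarray, cfg: EncoderConfig) -> np.ndarray:
    return ImageEncoder(cfg).encode(patch)


# ---------------------------------------------------------------------------
# similarity and contrastive objective
# ---------------------------------------------------------------------------


def _unit_rows(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise InputError("cannot normalize a zero embedding")
    return x / norms


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two non-zero vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise InputError("cosine similarity undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def cosine_similarity_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities between rows of ``a`` and rows of ``b``."""
    return _unit_rows(np.atleast_2d(a)) @ _unit_rows(np.atleast_2d(b)).T


def contrastive_loss(x: np.ndarray, y: np.ndarray, sigma: float = 0.07) -> float:
    """Symmetric InfoNCE loss over a batch of paired embeddings.

    ``x`` (image) and ``y`` (text) are N x d; rows are L2-normalized before
    the logits ``x_i . y_j / sigma`` are formed.  Both the image-to-text and
    the text-to-image softmax terms are averaged over the batch.
    """
    loss, _, _ = contrastive_loss_and_grad(x, y, sigma)
    return loss


def contrastive_loss_and_grad(
    x: np.ndarray, y: np.ndarray, sigma: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss plus gradients with respect to the *raw* (unnormalized) embeddings."""
    if sigma <= 0:
        raise InputError("temperature sigma must be positive")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise InputError("image and text batches must have identical shape")
    n = x.shape[0]
    xn = np.linalg.norm(x, axis=1, keepdims=True)
    yn = np.linalg.norm(y, axis=1, keepdims=True)
    if np.any(xn == 0) or np.any(yn == 0):
        raise InputError("zero embedding in contrastive batch")
    u, v = x / xn, y / yn
    s = u @ v.T / sigma

    def log_softmax_rows(m):
        m = m - m.max(axis=1, keepdims=True)
        return m - np.log(np.exp(m).sum(axis=1, keepdims=True))

    ls_uv = log_softmax_rows(s)
    ls_vu = log_softmax_rows(s.T)
    loss = -(np.trace(ls_uv) + np.trace(ls_vu)) / n

    p = np.exp(ls_uv)
    q = np.exp(ls_vu)
    ds = ((p - np.eye(n)) + (q - np.eye(n)).T) / n / sigma
    du = ds @ v
    dv = ds.T @ u
    # backprop through row normalization: d(a/|a|) = (g - (g.u) u) / |a|
    dx = (du - (du * u).sum(axis=1, keepdims=True) * u) / xn
    dy = (dv - (dv * v).sum(axis=1, keepdims=True) * v) / yn
    return float(loss), dx, dy


# ---------------------------------------------------------------------------
# adapter fine-tuning
# ---------------------------------------------------------------------------


@dataclass
class AdapterPair:
    """Linear adapter heads on top of the frozen reference embeddings."""

    image_head: np.ndarray
    text_head: np.ndarray
    loss_trace: list[float] = field(default_factory=list)

    def apply_image(self, embs: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(embs, dtype=float)) @ self.image_head

    def apply_text(self, embs: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(embs, dtype=float)) @ self.text_head


def finetune_adapters(
    image_embs: np.ndarray,
    text_embs: np.ndarray,
    epochs: int = 10,
    cfg: EncoderConfig | None = None,
    batch_size: int = 64,
    lr: float = 0.5,
) -> AdapterPair:
    """Train linear adapter heads by minibatch gradient descent on InfoNCE.

    Heads are identity-initialized, so zero epochs leaves embeddings
    unchanged.  The per-epoch trace records the full-batch loss before any
    step (epoch 0) and after each epoch.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or EncoderConfig()
    if epochs < 0:
        raise InputError("epochs must be >= 0")
    x = np.atleast_2d(np.asarray(image_embs, dtype=float))
    y = np.atleast_2d(np.asarray(text_embs, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise InputError("image and text batches differ in size")
    if x.shape[0] < 2:
        raise InputError("need at least 2 pairs to form a contrastive batch")
    d_img, d_txt = x.shape[1], y.shape[1]
    a = np.eye(d_img, cfg.embed_dim) if d_img != cfg.embed_dim else np.eye(d_img)
    b = np.eye(d_txt, cfg.embed_dim) if d_txt != cfg.embed_dim else np.eye(d_txt)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xADA7]))

    trace = [contrastive_loss(x @ a, y @ b, cfg.temperature)]
    n = x.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            if idx.size < 2:
                continue
            _, dxa, dyb = contrastive_loss_and_grad(
                x[idx] @ a, y[idx] @ b, cfg.temperature
            )
            a -= lr * (x[idx].T @ dxa)
            b -= lr * (y[idx].T @ dyb)
        trace.append(contrastive_loss(x @ a, y @ b, cfg.temperature))
    return AdapterPair(image_head=a, text_head=b, loss_trace=trace)
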