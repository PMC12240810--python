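"""Cell-type decomposition by probabilistic mapping in embedding space.

A reference set of single cells (or cell clusters) is mapped onto spatial
locations by optimizing a spots-by-cells probability matrix M: the mapped
reference embeddings M S should resemble the target embeddings G column by
column, measured by cosine distance.  Each cell's column of M is a softmax
over spots, so it is a probability distribution over locations at every
optimizer step.  Per-spot cell-type fractions follow by summing M over the
cells of each type (weighted by cluster size), and an optional
non-maximum-suppression (NMS) refinement keeps only the most probable type
per spot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .st_io import InputError

logger = logging.getLogger("loki")

__all__ = [
    "MappingProblem",
    "MappingResult",
    "cluster_profiles",
    "map_cells",
    "fractions_from_mapping",
    "nms_refine",
    "evaluate_decomposition",
]


@dataclass
class MappingProblem:
    """Reference embeddings S (cells x d), target embeddings G (spots x d)."""

    S: np.ndarray
    G: np.ndarray
    cell_types: list[str]
    cluster_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        if self.S.shape[1] != self.G.shape[1]:
            raise InputError("reference and target embedding dimensions differ")
        if len(self.cell_types) != self.S.shape[0]:
            raise InputError("cell_types must label every reference row")
        if not np.isfinite(self.S).all() or not np.isfinite(self.G).all():
            raise InputError("embeddings contain non-finite values")
        if self.cluster_sizes is not None:
            self.cluster_sizes = np.asarray(self.cluster_sizes, dtype=float)
            if self.cluster_sizes.shape[0] != self.S.shape[0]:
                raise InputError("cluster_sizes must match reference rows")


@dataclass
class MappingResult:
    """Optimized mapping matrix (spots x cells) with its loss trace."""

    M: np.ndarray
    loss_trace: list[float] = field(default_factory=list)


def cluster_profiles(
    cell_embs: np.ndarray, labels
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Collapse cells to per-cluster mean embeddings with recorded sizes."""
    cell_embs = np.atleast_2d(np.asarray(cell_embs, dtype=float))
    labels = np.asarray(labels)
    if labels.shape[0] != cell_embs.shape[0]:
        raise InputError("labels must cover every cell")
    uniq = list(pd.unique(labels))
    means, sizes = [], []
    for lab in uniq:
        members = cell_embs[labels == lab]
        means.append(members.mean(axis=0))
        sizes.append(len(members))
    return np.stack(means), [str(u) for u in uniq], np.asarray(sizes, dtype=float)


def _softmax_columns(theta: np.ndarray) -> np.ndarray:
    z = theta - theta.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def _mapping_loss_and_grad(
    m: np.ndarray, s: np.ndarray, g: np.ndarray
) -> tuple[float, np.ndarray]:
    """Loss sum_k cosdist((M S)[:,k], G[:,k]) and its gradient wrt M."""
    a = m @ s  # spots x d
    a_norm = np.linalg.norm(a, axis=0)
    g_norm = np.linalg.norm(g, axis=0)
    an = np.maximum(a_norm, 1e-12)
    gn = np.maximum(g_norm, 1e-12)
    dots = (a * g).sum(axis=0)
    cos = dots / (an * gn)
    loss = float(np.sum(1.0 - cos))
    # d(-cos_k)/dA[:,k] = -(g_k/(|a||g|) - cos_k a_k/|a|^2)
    da = -(g / (an * gn)[None, :] - (cos / an**2)[None, :] * a)
    return loss, da @ s.T


def map_cells(
    problem: MappingProblem,
    lr: float = 0.1,
    epochs: int = 1000,
    seed: int = 0,
) -> MappingResult:
    """Optimize the spots-by-cells mapping matrix by gradient descent.

    M is parameterized as a columnwise softmax of an unconstrained matrix,
    so every cell's column stays a probability distribution over spots.
    The density prior over spots is uniform: no additional per-spot count
    or density term enters the loss.  Deterministic given ``seed``.
    """
    s, g = problem.S, problem.G
    n_spots, n_cells = g.shape[0], s.shape[0]
    rng = np.random.default_rng(seed)
    theta = 0.01 * rng.standard_normal((n_spots, n_cells))
    trace: list[float] = []
    for _ in range(epochs):
        m = _softmax_columns(theta)
        loss, dm = _mapping_loss_and_grad(m, s, g)
        if not np.isfinite(loss):
            raise InputError("mapping loss became non-finite; check embeddings")
        trace.append(loss)
        # softmax backprop per column
        dtheta = m * (dm - (dm * m).sum(axis=0, keepdims=True))
        theta -= lr * dtheta
    m = _softmax_columns(theta)
    final_loss, _ = _mapping_loss_and_grad(m, s, g)
    trace.append(final_loss)
    return MappingResult(M=m, loss_trace=trace)


def fractions_from_mapping(
    m: np.ndarray,
    cell_types: list[str],
    cluster_sizes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-spot cell-type probabilities from a mapping matrix.

    Sums each spot's mapping mass over the cells of each type (weighted by
    cluster size when mapping was done at cluster level) and row-normalizes.
    """
    m = np.atleast_2d(np.asarray(m, dtype=float))
    if len(cell_types) != m.shape[1]:
        raise InputError("cell_types must label every mapping column")
    sizes = (
        np.ones(m.shape[1])
        if cluster_sizes is None
        else np.asarray(cluster_sizes, dtype=float)
    )
    types = list(pd.unique(np.asarray(cell_types)))
    p = np.zeros((m.shape[0], len(types)))
    for j, t in enumerate(types):
        cols = [i for i, c in enumerate(cell_types) if c == t]
        p[:, j] = (m[:, cols] * sizes[cols][None, :]).sum(axis=1)
    row_sums = p.sum(axis=1)
    zero = row_sums == 0
    if zero.any():
        logger.warning(
            "fractions_from_mapping: %d spot(s) with zero mass set to uniform",
            int(zero.sum()),
        )
        p[zero] = 1.0 / len(types)
        row_sums[zero] = 1.0
    p /= row_sums[:, None]
    return pd.DataFrame(p, columns=[str(t) for t in types])


def type_zscores(p: pd.DataFrame) -> pd.DataFrame:
    """Per-type z-score of probabilities across spots (display scaling)."""
    arr = p.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return pd.DataFrame((arr - arr.mean(axis=0)) / sd, columns=p.columns, index=p.index)


def nms_refine(p: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Keep only the most probable cell type per spot at its original value.

    All competing types are zeroed; argmax ties resolve to the lowest type
    index.  Idempotent.
    """
    frame = isinstance(p, pd.DataFrame)
    arr = np.atleast_2d(np.asarray(p, dtype=float))
    out = np.zeros_like(arr)
    best = arr.argmax(axis=1)
    rows = np.arange(arr.shape[0])
    out[rows, best] = arr[rows, best]
    if frame:
        return pd.DataFrame(out, columns=p.columns, index=p.index)
    return out


def evaluate_decomposition(
    pred: pd.DataFrame | np.ndarray, truth: pd.DataFrame | np.ndarray
) -> pd.DataFrame:
    """Per-type JS divergence and SSIM between predicted and true type maps.

    Each type's spot vector is normalized to a probability distribution over
    spots for the JS divergence; SSIM treats the raw per-type spot map as an
    image with a single global window.
    """
    if isinstance(pred, pd.DataFrame) and isinstance(truth, pd.DataFrame):
        if list(pred.columns) != list(truth.columns):
            raise InputError("prediction and truth type labels differ")
        labels = [str(c) for c in pred.columns]
    else:
        labels = None
    p = np.atleast_2d(np.asarray(pred, dtype=float))
    q = np.atleast_2d(np.asarray(truth, dtype=float))
    if p.shape != q.shape:
        raise InputError("prediction and truth shapes differ")
    rows = []
    for j in range(p.shape[1]):
        a, b = p[:, j], q[:, j]
        sa, sb = a.sum(), b.sum()
        if sa == 0 or sb == 0:
            js = 1.0 if (sa > 0) != (sb > 0) else 0.0
        else:
            js = metrics.js_divergence(a / sa, b / sb)
        rows.append(
            {
                "type": labels[j] if labels else str(j),
                "js": js,
                "ssim": metrics.ssim(a, b),
            }
        )
    return pd.DataFrame(rows).set_index("type")
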