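"""Embedding-augmented nonrigid point-set registration of tissue sections.

Registration uses coherent point drift (CPD): the moving (source) section is
modelled as Gaussian-mixture centroids that drift coherently toward the
fixed (target) section, alternating an E-step (soft correspondences) with an
M-step (a smoothness-regularized displacement field).  Each spot is
represented by its two spatial coordinates augmented with the first two
principal components of its embedding, so transcriptionally similar regions
attract each other during registration; the M-step updates displace the
spatial coordinates only.  A final rigid (rotation + translation) projection
of the nonrigid fit is returned by default to suppress distortion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.decomposition import PCA

from . import metrics
from .st_io import InputError, SpotMatrix

logger = logging.getLogger("loki")

__all__ = [
    "PointSet",
    "CpdParams",
    "AlignmentResult",
    "augment_points",
    "augment_pair",
    "init_sigma2",
    "gaussian_kernel",
    "estep_posterior",
    "mstep_update",
    "cpd_align",
    "rigid_projection",
    "align_sections",
    "evaluate_alignment",
]


@dataclass
class PointSet:
    """Spot coordinates plus optional embedding-derived feature columns.

    ``spatial`` holds standardized coordinates used inside CPD;
    ``spatial_mean``/``spatial_std`` retain the standardization so results
    can be mapped back to the original coordinate units.
    """

    spatial: np.ndarray
    features: np.ndarray
    spatial_mean: np.ndarray = field(default_factory=lambda: np.zeros(2))
    spatial_std: np.ndarray = field(default_factory=lambda: np.ones(2))

    def __post_init__(self) -> None:
        self.spatial = np.atleast_2d(np.asarray(self.spatial, dtype=float))
        self.features = np.asarray(self.features, dtype=float)
        if self.features.size == 0:
            self.features = np.zeros((self.spatial.shape[0], 0))
        if self.spatial.shape[0] < 3:
            raise InputError("registration needs at least 3 points")
        if not np.isfinite(self.spatial).all() or not np.isfinite(self.features).all():
            raise InputError("point set contains non-finite values")
        if self.features.shape[0] != self.spatial.shape[0]:
            raise InputError("feature rows do not match spatial rows")

    @property
    def n(self) -> int:
        return self.spatial.shape[0]

    @property
    def dim(self) -> int:
        return self.spatial.shape[1] + self.features.shape[1]

    @property
    def data(self) -> np.ndarray:
        return np.hstack([self.spatial, self.features])

    def to_original_units(self, spatial: np.ndarray) -> np.ndarray:
        return spatial * self.spatial_std + self.spatial_mean


@dataclass
class CpdParams:
    """CPD hyperparameters on standardized coordinates.

    ``beta`` is the Gaussian kernel width controlling deformation stiffness,
    ``lam`` the smoothness regularization weight, ``w`` the outlier mixture
    weight, ``feature_scale`` multiplies the embedding feature columns after
    z-scoring, and ``clip_w`` optionally clamps the transform coefficients
    to [0, 1] (off by default; the constraint is dimensionally inconsistent
    for a displacement-coefficient matrix).
    """

    beta: float = 2.0
    lam: float = 2.0
    w: float = 0.0
    max_iter: int = 100
    tol: float = 1e-5
    feature_scale: float = 1.0
    clip_w: bool = False

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.lam <= 0:
            raise InputError("beta and lambda must be positive")
        if not (0 <= self.w < 1):
            raise InputError("outlier weight w must lie in [0, 1)")
        if self.feature_scale < 0:
            raise InputError("feature_scale must be non-negative")


@dataclass
class AlignmentResult:
    """Nonrigid CPD fit plus its rigid projection, in target units."""

    coordinates: np.ndarray  # default output (rigid-projected)
    nonrigid: np.ndarray  # raw CPD-transformed source coordinates
    W: np.ndarray
    sigma2_trace: list[float]
    rotation: np.ndarray
    translation: np.ndarray
    converged: bool
    posterior: np.ndarray | None = None


def _standardize_columns(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    return (x - mean) / std, mean, std


def augment_points(
    coords: np.ndarray,
    embeddings: np.ndarray | None = None,
    feature_scale: float = 1.0,
    pca: PCA | None = None,
    feature_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> PointSet:
    """Build a 4-D point set: standardized coordinates + 2 embedding PCs.

    The first two principal components of the embeddings are appended to the
    spot coordinates; spatial and feature columns are z-scored independently
    and the features multiplied by ``feature_scale``.  A fitted ``pca`` (and
    matching feature ``(mean, std)`` stats) may be supplied so two sections
    share one comparable feature basis.  Embeddings with fewer than two
    informative components fall back to 1 or 0 feature columns.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    spatial, mean, std = _standardize_columns(coords)
    if embeddings is None:
        return PointSet(spatial, np.zeros((coords.shape[0], 0)), mean, std)
    embeddings = np.atleast_2d(np.asarray(embeddings, dtype=float))
    if pca is None:
        pca = PCA(n_components=min(2, embeddings.shape[1], embeddings.shape[0] - 1))
        pca.fit(embeddings)
    scores = pca.transform(embeddings)
    keep = pca.explained_variance_ > 1e-12
    scores = scores[:, keep]
    if scores.shape[1] < 2:
        logger.warning(
            "augment_points: embeddings rank-deficient, using %d feature column(s)",
            scores.shape[1],
        )
    if scores.shape[1] == 0:
        return PointSet(spatial, scores, mean, std)
    if feature_stats is None:
        features, _, _ = _standardize_columns(scores)
    else:
        f_mean, f_std = feature_stats
        features = (scores - f_mean[: scores.shape[1]]) / f_std[: scores.shape[1]]
    return PointSet(spatial, features * feature_scale, mean, std)


def augment_pair(
    source_coords: np.ndarray,
    source_embs: np.ndarray,
    target_coords: np.ndarray,
    target_embs: np.ndarray,
    feature_scale: float = 1.0,
) -> tuple[PointSet, PointSet]:
    """Augment two sections with one PCA basis fitted on their pooled embeddings.

    A shared basis (and pooled feature standardization) keeps the feature
    columns of the two sections directly comparable, which is what lets the
    E-step match transcriptionally similar regions across sections.
    """
    source_embs = np.atleast_2d(np.asarray(source_embs, dtype=float))
    target_embs = np.atleast_2d(np.asarray(target_embs, dtype=float))
    pooled = np.vstack([source_embs, target_embs])
    pca = PCA(n_components=min(2, pooled.shape[1], pooled.shape[0] - 1))
    pca.fit(pooled)
    scores = pca.transform(pooled)
    keep = pca.explained_variance_ > 1e-12
    f_mean = scores.mean(axis=0)
    f_std = scores.std(axis=0)
    f_std = np.where(f_std == 0, 1.0, f_std)
    src = augment_points(
        source_coords, source_embs, feature_scale, pca=pca, feature_stats=(f_mean, f_std)
    )
    tgt = augment_points(
        target_coords, target_embs, feature_scale, pca=pca, feature_stats=(f_mean, f_std)
    )
    n_keep = int(keep.sum())
    if src.features.shape[1] != n_keep:
        src = PointSet(src.spatial, src.features[:, keep], src.spatial_mean, src.spatial_std)
        tgt = PointSet(tgt.spatial, tgt.features[:, keep], tgt.spatial_mean, tgt.spatial_std)
    return src, tgt


# ---------------------------------------------------------------------------
# CPD building blocks
# ---------------------------------------------------------------------------


def init_sigma2(x: np.ndarray, y: np.ndarray) -> float:
    """Initial displacement variance: mean squared distance over all pairs and dims."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise InputError("point sets differ in dimensionality")
    d = x.shape[1]
    diff2 = ((x[:, None, :] - y[None, :, :]) ** 2).sum()
    sigma2 = diff2 / (d * x.shape[0] * y.shape[0])
    if sigma2 <= 0:
        logger.warning("init_sigma2: zero displacement variance, flooring at 1e-12")
        return 1e-12
    return float(sigma2)


def gaussian_kernel(y: np.ndarray, beta: float) -> np.ndarray:
    """Smoothness kernel ``g_ij = exp(-|y_i - y_j|^2 / (2 beta^2))``."""
    if beta <= 0:
        raise InputError("beta must be positive")
    y = np.atleast_2d(np.asarray(y, dtype=float))
    d2 = ((y[:, None, :] - y[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2 * beta**2))


def estep_posterior(
    x: np.ndarray, t: np.ndarray, sigma2: float, w: float = 0.0
) -> np.ndarray:
    """Posterior correspondence matrix P (sources x targets).

    Computed in log space.  With outlier weight ``w`` the column sums are at
    most 1; with ``w = 0`` each column sums to exactly 1.
    """
    if sigma2 <= 0:
        raise InputError("sigma2 must be positive")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    t = np.atleast_2d(np.asarray(t, dtype=float))
    n, m, d = x.shape[0], t.shape[0], x.shape[1]
    d2 = ((t[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)  # m x n
    log_num = -d2 / (2 * sigma2)
    if w > 0:
        log_outlier = (
            np.log(w / (1 - w)) + (d / 2) * np.log(2 * np.pi * sigma2) + np.log(m / n)
        )
        log_den = np.logaddexp(logsumexp(log_num, axis=0), log_outlier)
    else:
        log_den = logsumexp(log_num, axis=0)
    return np.exp(log_num - log_den[None, :])


def mstep_update(
    x: np.ndarray,
    y: np.ndarray,
    g: np.ndarray,
    p: np.ndarray,
    lam: float,
    sigma2: float,
    n_spatial: int | None = None,
    clip_w: bool = False,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One CPD M-step: solve for W, transform, and update sigma^2.

    Solves ``(G + lam sigma2 d(P1)^{-1}) W = d(P1)^{-1} P X - Y`` for the
    spatial columns only (feature columns of W are identically zero, so the
    embedding feature coordinates are never deformed), forms ``T = Y + GW``
    and re-estimates sigma^2 from the trace identity over all dimensions.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    m, d = y.shape
    if n_spatial is None:
        n_spatial = d
    p1 = p.sum(axis=1)  # row sums, length m
    p1 = np.maximum(p1, 1e-12)
    pt1 = p.sum(axis=0)  # column sums, length n
    px = p @ x
    lhs = g + lam * sigma2 * np.diag(1.0 / p1)
    rhs = px / p1[:, None] - y
    try:
        w_full = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.trace(lhs) / m
        logger.warning("mstep_update: singular system, adding ridge jitter %.3e", jitter)
        w_full = np.linalg.solve(lhs + jitter * np.eye(m), rhs)
    w_full[:, n_spatial:] = 0.0
    if clip_w:
        w_full = np.clip(w_full, 0.0, 1.0)
    t = y + g @ w_full
    np_total = p.sum()
    term = (
        (pt1 * (x**2).sum(axis=1)).sum()
        - 2.0 * (px * t).sum()
        + (p1 * (t**2).sum(axis=1)).sum()
    )
    sigma2_new = term / (np_total * d)
    sigma2_new = max(float(sigma2_new), 1e-12)
    return w_full, t, sigma2_new


def cpd_align(
    source: PointSet, target: PointSet, params: CpdParams | None = None
) -> AlignmentResult:
    """Register ``source`` onto ``target`` with embedding-augmented CPD.

    Iterates E/M steps until the relative change in sigma^2 drops below
    ``params.tol`` or ``params.max_iter`` is reached, then fits the rigid
    rotation + translation between the source spots before and after the
    nonrigid alignment.  The default output coordinates are the rigid
    projection (in the target's original units); the raw nonrigid fit is
    also returned.
    """
    params = params or CpdParams()
    if source.dim != target.dim:
        raise InputError("source and target point sets differ in dimensionality")
    x = target.data
    y = source.data
    g = gaussian_kernel(y, params.beta)
    sigma2 = init_sigma2(x, y)
    trace = [sigma2]
    t = y.copy()
    w_mat = np.zeros_like(y)
    p = None
    converged = False
    n_spatial = source.spatial.shape[1]
    for _ in range(params.max_iter):
        p = estep_posterior(x, t, sigma2, params.w)
        w_mat, t, sigma2_new = mstep_update(
            x, y, g, p, params.lam, sigma2, n_spatial=n_spatial, clip_w=params.clip_w
        )
        trace.append(sigma2_new)
        if abs(sigma2_new - sigma2) / max(sigma2, 1e-300) < params.tol:
            sigma2 = sigma2_new
            converged = True
            break
        sigma2 = sigma2_new
    if not converged:
        logger.warning("cpd_align: no convergence after %d iterations", params.max_iter)

    nonrigid = target.to_original_units(t[:, :n_spatial])
    source_orig = source.to_original_units(source.spatial)
    rot, trans = rigid_projection(source_orig, nonrigid)
    rigid_coords = source_orig @ rot.T + trans
    return AlignmentResult(
        coordinates=rigid_coords,
        nonrigid=nonrigid,
        W=w_mat,
        sigma2_trace=trace,
        rotation=rot,
        translation=trans,
        converged=converged,
        posterior=p,
    )


def rigid_projection(before: np.ndarray, after: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation + translation mapping ``before`` onto ``after``.

    Orthogonal Procrustes without scaling (Kabsch); the rotation has
    determinant +1, so the projection is an exact isometry.
    """
    before = np.atleast_2d(np.asarray(before, dtype=float))
    after = np.atleast_2d(np.asarray(after, dtype=float))
    b_mean = before.mean(axis=0)
    a_mean = after.mean(axis=0)
    h = (before - b_mean).T @ (after - a_mean)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(vt.T @ u.T)
    rot = vt.T @ np.diag([1.0, np.sign(det)]) @ u.T
    trans = a_mean - rot @ b_mean
    return rot, trans


def align_sections(
    source_coords: np.ndarray,
    target_coords: np.ndarray,
    source_embs: np.ndarray | None = None,
    target_embs: np.ndarray | None = None,
    params: CpdParams | None = None,
) -> AlignmentResult:
    """Convenience wrapper: augment both sections (shared basis) and run CPD."""
    params = params or CpdParams()
    if source_embs is None or target_embs is None:
        src = augment_points(source_coords)
        tgt = augment_points(target_coords)
    else:
        src, tgt = augment_pair(
            source_coords, source_embs, target_coords, target_embs, params.feature_scale
        )
    return cpd_align(src, tgt, params)


def evaluate_alignment(
    aligned_coords: np.ndarray,
    aligned_expr: SpotMatrix,
    target: SpotMatrix,
    top_genes: int = 2000,
) -> dict:
    """Expression agreement between aligned source spots and their nearest target spot.

    For each aligned spot the nearest target spot is found; Pearson and
    Kendall-tau correlations of the ``top_genes`` most variable shared genes
    are computed per matched pair and summarized by the median.
    """
    shared = [g for g in aligned_expr.gene_ids if g in set(target.gene_ids)]
    if len(shared) < 2:
        raise InputError("fewer than 2 shared genes; correlations undefined")
    src_idx = [aligned_expr.gene_ids.index(g) for g in shared]
    tgt_idx = [target.gene_ids.index(g) for g in shared]
    src = aligned_expr.to_dense()[src_idx]
    tgt = target.to_dense()[tgt_idx]
    variances = tgt.var(axis=1)
    order = np.argsort(-variances, kind="stable")[: min(top_genes, len(shared))]
    src, tgt = src[order], tgt[order]

    aligned_coords = np.atleast_2d(np.asarray(aligned_coords, dtype=float))
    d2 = ((aligned_coords[:, None, :] - target.coords[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    pccs, taus = [], []
    for j, tj in enumerate(nearest):
        a, b = src[:, j], tgt[:, tj]
        if a.std() == 0 or b.std() == 0:
            continue
        pccs.append(metrics.pearson(a, b))
        taus.append(metrics.kendall_tau(a, b))
    return {
        "pcc": np.array(pccs),
        "tau": np.array(taus),
        "median_pcc": float(np.median(pccs)) if pccs else float("nan"),
        "median_tau": float(np.median(taus)) if taus else float("nan"),
        "matched_target_index": nearest,
    }
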