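"""Evaluation metrics implemented directly from their defining formulas.

Covers the Calinski–Harabasz variance-ratio criterion, Pearson correlation,
Kendall's tau-b, Jensen–Shannon divergence (base-2 logs, so the value lies
in [0, 1]), a global single-window SSIM over spot-value maps, mean squared
error, weighted-F1 classification scores, and the cross-method "impact
score" that averages the SSIM z-score with the sign-inverted JS z-score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .st_io import InputError

__all__ = [
    "calinski_harabasz",
    "pearson",
    "kendall_tau",
    "js_divergence",
    "kl_divergence",
    "ssim",
    "mse",
    "classification_report",
    "MethodSummary",
    "impact_score",
]


def calinski_harabasz(points: np.ndarray, labels) -> float:
    """Variance-ratio criterion ``(BCSS/(k-1)) / (WCSS/(n-k))``.

    BCSS is the size-weighted squared distance of cluster centroids from the
    overall centroid; WCSS the total squared distance of points from their
    cluster centroid.  Higher is better-separated clustering.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    labels = np.asarray(labels)
    if labels.shape[0] != points.shape[0]:
        raise InputError("labels and points differ in length")
    uniq = pd.unique(labels)
    n, k = points.shape[0], len(uniq)
    if k < 2:
        raise InputError("CH score needs at least 2 clusters")
    if k >= n:
        raise InputError("CH score needs fewer clusters than points")
    overall = points.mean(axis=0)
    bcss = 0.0
    wcss = 0.0
    for lab in uniq:
        members = points[labels == lab]
        centroid = members.mean(axis=0)
        bcss += len(members) * float(((centroid - overall) ** 2).sum())
        wcss += float(((members - centroid) ** 2).sum())
    if wcss == 0:
        raise InputError("within-cluster dispersion is zero; CH score undefined")
    return (bcss / (k - 1)) / (wcss / (n - k))


def pearson(x, y) -> float:
    """Pearson correlation coefficient of two paired series."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise InputError("need two equal-length series of length >= 2")
    n = x.size
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(
        n * (y**2).sum() - y.sum() ** 2
    )
    if den == 0:
        raise InputError("correlation undefined for a constant series")
    return float(num / den)


def kendall_tau(x, y) -> float:
    """Kendall's tau-b: ``(P-Q)/sqrt((P+Q+T)(P+Q+U))``.

    P/Q count concordant/discordant pairs; T and U count pairs tied solely
    in x or solely in y.  Pairs tied in both are excluded from all four.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise InputError("need two equal-length series of length >= 2")
    i, j = np.triu_indices(x.size, k=1)
    dx = np.sign(x[i] - x[j])
    dy = np.sign(y[i] - y[j])
    p = int(np.sum((dx * dy) > 0))
    q = int(np.sum((dx * dy) < 0))
    t = int(np.sum((dx == 0) & (dy != 0)))
    u = int(np.sum((dx != 0) & (dy == 0)))
    if p + q + t == 0 or p + q + u == 0:
        raise InputError("tau undefined: all pairs tied in one series")
    return float((p - q) / np.sqrt((p + q + t) * (p + q + u)))


def _check_simplex(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if (p < 0).any():
        raise InputError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > 1e-9:
        raise InputError(f"{name} does not sum to 1")
    return p


def kl_divergence(p, q) -> float:
    """KL(P||Q) with base-2 logarithms; 0*log(0/.) terms are 0."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def js_divergence(p, q) -> float:
    """Jensen–Shannon divergence of two distributions, in [0, 1] (base-2)."""
    p = _check_simplex(p, "P")
    q = _check_simplex(q, "Q")
    if p.size != q.size:
        raise InputError("P and Q differ in length")
    m = 0.5 * (p + q)
    return 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)


def ssim(x, y, data_range: float | None = None) -> float:
    """Global single-window structural similarity of two value maps.

    The two maps are compared as flat value vectors with a single window
    covering all locations — spot maps are irregular point sets, not
    rasters.  Constants are ``C1=(0.01 L)^2`` and ``C2=(0.03 L)^2`` with
    ``L`` the pooled value range (floored at 1e-8); variances use the
    population convention.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise InputError("need two equal-length maps with >= 2 locations")
    if data_range is None:
        pooled = np.concatenate([x, y])
        data_range = float(pooled.max() - pooled.min())
    data_range = max(data_range, 1e-8)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float(
        ((2 * mx * my + c1) * (2 * cov + c2))
        / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )


def mse(a, b) -> float:
    """Mean squared elementwise difference of two equal-shape arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def classification_report(pred, truth) -> pd.DataFrame:
    """Per-class precision/recall/F1 plus a frequency-weighted F1 row.

    F1 = 2 TP / (2 TP + FP + FN); the weighted average weights each class
    by its frequency among the true labels.
    """
    pred = list(pred)
    truth = list(truth)
    if not truth or len(pred) != len(truth):
        raise InputError("prediction and truth must be equal-length and non-empty")
    classes = list(pd.unique(np.asarray(truth + pred)))
    rows = []
    for c in classes:
        tp = sum(1 for p, t in zip(pred, truth) if p == c and t == c)
        fp = sum(1 for p, t in zip(pred, truth) if p == c and t != c)
        fn = sum(1 for p, t in zip(pred, truth) if p != c and t == c)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        rows.append(
            {
                "label": c,
                "support": sum(1 for t in truth if t == c),
                "precision": precision,
                "recall": recall,
                "f1": f1,
            }
        )
    report = pd.DataFrame(rows).set_index("label")
    report.attrs["weighted_f1"] = float(
        (report["f1"] * report["support"]).sum() / max(report["support"].sum(), 1)
    )
    return report


def weighted_f1(pred, truth) -> float:
    return classification_report(pred, truth).attrs["weighted_f1"]


@dataclass(frozen=True)
class MethodSummary:
    """A method's mean SSIM and mean JS divergence across cell types."""

    name: str
    mean_ssim: float
    mean_js: float


def impact_score(methods: list[MethodSummary]) -> pd.DataFrame:
    """Cross-method impact score: mean of SSIM z-score and -JS z-score.

    Z-scores use the population standard deviation across methods; the JS
    z-score is sign-inverted so that lower divergence scores higher.  If a
    metric has zero variance across methods its z-scores are all 0.
    """
    if len(methods) < 2:
        raise InputError("impact score needs at least 2 methods")
    ssim_vals = np.array([m.mean_ssim for m in methods], dtype=float)
    js_vals = np.array([m.mean_js for m in methods], dtype=float)

    def zscores(v):
        sd = v.std()  # population
        if sd == 0:
            return np.zeros_like(v)
        return (v - v.mean()) / sd

    z_ssim = zscores(ssim_vals)
    z_js = -zscores(js_vals)
    impact = (z_ssim + z_js) / 2.0
    out = pd.DataFrame(
        {
            "method": [m.name for m in methods],
            "mean_ssim": ssim_vals,
            "mean_js": js_vals,
            "z_ssim": z_ssim,
            "z_js": z_js,
            "impact": impact,
        }
    ).set_index("method")
    return out.sort_values("impact", ascending=False)
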