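"""Seeded generators for paired expression/image cohorts and perturbations.

The central generator emulates the paired structure of a Visium-style
experiment: every spot carries a latent cell-type mixture, its counts are
negative-binomial draws from type-specific gene loadings, and its image
feature vector is a linear readout of the same mixture plus Gaussian noise.
Mixtures vary smoothly in space (each type concentrates around a spatial
archetype center), so embeddings are spatially informative — the property
both alignment and decomposition rely on.

Further generators produce spatially perturbed adjacent sections with the
exact inverse transform recorded, depth-downsampled counts by binomial
thinning, pseudo-spot-binned single-cell data, and additive image noise.
All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .st_io import InputError, SpotMatrix

__all__ = [
    "CohortSpec",
    "PerturbSpec",
    "PairedCohort",
    "simulate_paired_cohort",
    "perturb_section",
    "downsample_depth",
    "make_pseudo_spots",
    "add_feature_noise",
]


@dataclass
class CohortSpec:
    """Parameters of a simulated paired expression/image cohort.

    ``concentration`` is the Dirichlet concentration of per-spot mixture
    fractions (smaller = purer spots); ``spatial_bandwidth`` (in units of
    grid spacing) sets how sharply each cell type concentrates around its
    spatial archetype; ``nb_dispersion`` is the negative-binomial size
    parameter (larger = closer to Poisson); ``feature_noise_sd`` is the
    Gaussian noise added to the linear image-feature readout of the
    fractions.
    """

    n_spots: int = 200
    n_genes: int = 300
    n_types: int = 4
    concentration: float = 0.5
    spatial_bandwidth: float = 4.0
    nb_dispersion: float = 10.0
    n_features: int = 32
    feature_noise_sd: float = 0.0
    library_size: tuple[int, int] = (2000, 4000)
    markers_per_type: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_spots, self.n_genes, self.n_types, self.n_features) <= 0:
            raise InputError("all cohort dimensions must be positive")
        if self.concentration <= 0 or self.nb_dispersion <= 0:
            raise InputError("concentration and dispersion must be positive")
        if self.feature_noise_sd < 0:
            raise InputError("feature_noise_sd must be non-negative")
        if self.library_size[0] <= 0 or self.library_size[1] < self.library_size[0]:
            raise InputError("library_size must be a positive (low, high) range")


@dataclass
class PairedCohort:
    """A simulated cohort: counts, coordinates, image features and the truth."""

    spots: SpotMatrix
    features: np.ndarray
    fractions: pd.DataFrame
    loadings: np.ndarray  # genes x types, column-normalized
    feature_map: np.ndarray  # n_features x types
    type_labels: list[str] = field(default_factory=list)


def _spot_grid(n_spots: int) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n_spots)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    coords = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    return coords[:n_spots]


def simulate_paired_cohort(spec: CohortSpec) -> PairedCohort:
    """Generate a paired expression/image cohort with known mixture truth."""
    rng = np.random.default_rng(spec.seed)
    coords = _spot_grid(spec.n_spots)

    # spatial archetypes: each type pulls mixture mass toward its center
    centers = coords.min(axis=0) + rng.uniform(
        0.1, 0.9, size=(spec.n_types, 2)
    ) * (coords.max(axis=0) - coords.min(axis=0) + 1e-12)
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    affinity = np.exp(-d2 / (2 * spec.spatial_bandwidth**2)) + 1e-3
    base = affinity / affinity.sum(axis=1, keepdims=True)
    fractions = np.stack(
        [
            rng.dirichlet(spec.concentration * spec.n_types * base[i] + 1e-3)
            for i in range(spec.n_spots)
        ]
    )

    # type-specific gene loadings: shared baseline plus disjoint marker blocks
    loadings = rng.gamma(1.0, 1.0, size=(spec.n_genes, spec.n_types))
    markers = min(spec.markers_per_type, spec.n_genes // spec.n_types)
    for t in range(spec.n_types):
        block = slice(t * markers, (t + 1) * markers)
        loadings[block, t] += rng.gamma(20.0, 1.0, size=markers)
    loadings /= loadings.sum(axis=0, keepdims=True)

    libraries = rng.integers(spec.library_size[0], spec.library_size[1] + 1, spec.n_spots)
    mu = (fractions @ loadings.T) * libraries[:, None]  # spots x genes
    # negative binomial via gamma-poisson mixture
    lam = rng.gamma(spec.nb_dispersion, mu / spec.nb_dispersion)
    counts = rng.poisson(lam).astype(float)

    feature_map = rng.standard_normal((spec.n_features, spec.n_types))
    features = fractions @ feature_map.T
    if spec.feature_noise_sd > 0:
        features = features + rng.normal(0, spec.feature_noise_sd, features.shape)

    type_labels = [f"type_{t}" for t in range(spec.n_types)]
    spots = SpotMatrix(
        counts=sp.csr_matrix(counts.T),
        gene_ids=[f"G{i:04d}" for i in range(spec.n_genes)],
        barcodes=[f"spot_{j:04d}" for j in range(spec.n_spots)],
        coords=coords,
        spot_diameter=1.0,
        meta={"simulated": True, "seed": spec.seed},
    )
    return PairedCohort(
        spots=spots,
        features=features,
        fractions=pd.DataFrame(fractions, columns=type_labels),
        loadings=loadings,
        feature_map=feature_map,
        type_labels=type_labels,
    )


@dataclass
class PerturbSpec:
    """An adjacent-section perturbation: rigid motion, jitter, count noise.

    ``resample_rate`` is the fraction of each spot's counts removed and
    re-drawn from the spot's own gene proportions (totals are conserved);
    ``jitter_sd`` is in coordinate units.  The ``low``/``high`` presets use
    10%/40% resampling and jitter of 0.25/1.0 times the spot spacing.
    """

    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    jitter_sd: float = 0.0
    resample_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise InputError("jitter_sd must be non-negative")
        if not 0 <= self.resample_rate <= 1:
            raise InputError("resample_rate must lie in [0, 1]")

    @classmethod
    def low(cls, spot_spacing: float = 1.0, rotation_deg: float = 10.0, seed: int = 0):
        return cls(
            rotation_deg=rotation_deg,
            translation=(2.0 * spot_spacing, -1.0 * spot_spacing),
            jitter_sd=0.25 * spot_spacing,
            resample_rate=0.10,
            seed=seed,
        )

    @classmethod
    def high(cls, spot_spacing: float = 1.0, rotation_deg: float = 25.0, seed: int = 0):
        return cls(
            rotation_deg=rotation_deg,
            translation=(4.0 * spot_spacing, -2.0 * spot_spacing),
            jitter_sd=1.0 * spot_spacing,
            resample_rate=0.40,
            seed=seed,
        )


def _rotation_matrix(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def perturb_section(m: SpotMatrix, spec: PerturbSpec) -> tuple[SpotMatrix, dict]:
    """Simulate an adjacent section: rigid motion + jitter + count resampling.

    Coordinates are rotated about the section centroid, translated, then
    jittered.  Returns the perturbed section and the ground-truth transform
    with its exact inverse (``R``, ``t``, centroid ``c``; forward is
    ``R (x - c) + c + t``).
    """
    rng = np.random.default_rng(spec.seed)
    rot = _rotation_matrix(spec.rotation_deg)
    center = m.coords.mean(axis=0)
    t = np.asarray(spec.translation, dtype=float)
    coords = (m.coords - center) @ rot.T + center + t
    if spec.jitter_sd > 0:
        coords = coords + rng.normal(0, spec.jitter_sd, coords.shape)

    counts = m.to_dense()
    if spec.resample_rate > 0:
        for j in range(counts.shape[1]):
            col = counts[:, j].astype(np.int64)
            total = int(col.sum())
            n_swap = int(round(spec.resample_rate * total))
            if total == 0 or n_swap == 0:
                continue
            removed = rng.multivariate_hypergeometric(col, n_swap)
            added = rng.multinomial(n_swap, col / total)
            counts[:, j] = col - removed + added

    perturbed = replace(
        m,
        counts=sp.csr_matrix(counts),
        coords=coords,
        meta={**m.meta, "perturbed": True},
    )
    truth = {
        "rotation": rot,
        "translation": t,
        "center": center,
        "inverse": lambda c: (np.atleast_2d(c) - center - t) @ rot + center,
        "true_coords": m.coords.copy(),
    }
    return perturbed, truth


def downsample_depth(m: SpotMatrix, target_depth: float, seed: int = 0) -> SpotMatrix:
    """Thin counts binomially so the median spot depth hits ``target_depth``."""
    if target_depth <= 0:
        raise InputError("target depth must be positive")
    depths = np.asarray(m.counts.sum(axis=0)).ravel()
    median = float(np.median(depths))
    if target_depth > median:
        raise InputError(
            f"target depth {target_depth} exceeds current median depth {median}"
        )
    p = target_depth / median
    rng = np.random.default_rng(seed)
    coo = sp.coo_matrix(m.counts)
    thinned = rng.binomial(coo.data.astype(np.int64), p)
    out = sp.csr_matrix(
        (thinned.astype(float), (coo.row, coo.col)), shape=m.counts.shape
    )
    out.eliminate_zeros()
    return replace(m, counts=out, meta={**m.meta, "downsampled_to": target_depth})


def make_pseudo_spots(
    cell_coords: np.ndarray,
    cell_expr: np.ndarray,
    gene_ids: list[str],
    spacing: float,
    diameter: float | None = None,
) -> tuple[SpotMatrix, np.ndarray]:
    """Bin single cells onto a spot grid, averaging member-cell expression.

    Cells are assigned to the nearest grid center within ``diameter / 2``
    (default ``diameter = spacing``); each pseudo-spot's profile is the mean
    of its member cells and empty spots are dropped.  Also returns the spot
    index assigned to each cell (-1 for unassigned).
    """
    cell_coords = np.atleast_2d(np.asarray(cell_coords, dtype=float))
    cell_expr = np.atleast_2d(np.asarray(cell_expr, dtype=float))
    if spacing <= 0:
        raise InputError("spot spacing must be positive")
    diameter = spacing if diameter is None else diameter
    lo = cell_coords.min(axis=0)
    hi = cell_coords.max(axis=0)
    xs = np.arange(lo[0], hi[0] + spacing, spacing)
    ys = np.arange(lo[1], hi[1] + spacing, spacing)
    centers = np.array([[x, y] for x in xs for y in ys])
    d2 = ((cell_coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    within = d2[np.arange(len(cell_coords)), nearest] <= (diameter / 2) ** 2
    assignment = np.where(within, nearest, -1)
    used = np.unique(assignment[assignment >= 0])
    if used.size == 0:
        raise InputError("no cell falls within any pseudo-spot")
    profiles = np.stack(
        [cell_expr[assignment == s].mean(axis=0) for s in used]
    )
    spots = SpotMatrix(
        counts=sp.csr_matrix(profiles.T),
        gene_ids=list(gene_ids),
        barcodes=[f"pseudo_{s}" for s in used],
        coords=centers[used],
        spot_diameter=diameter,
        meta={"pseudo_visium": True},
    )
    remap = {s: i for i, s in enumerate(used)}
    return spots, np.array([remap.get(a, -1) for a in assignment])


def add_feature_noise(features: np.ndarray, sd: float, seed: int = 0) -> np.ndarray:
    """Add elementwise Gaussian noise (degraded-image simulation)."""
    if sd < 0:
        raise InputError("noise sd must be non-negative")
    features = np.asarray(features, dtype=float)
    if sd == 0:
        return features.copy()
    rng = np.random.default_rng(seed)
    return features + rng.normal(0, sd, features.shape)
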