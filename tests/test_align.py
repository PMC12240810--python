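import numpy as np
import pytest

from loki import align, simdata
from loki.align import (
    CpdParams,
    PointSet,
    augment_pair,
    augment_points,
    cpd_align,
    estep_posterior,
    evaluate_alignment,
    gaussian_kernel,
    init_sigma2,
    mstep_update,
    rigid_projection,
)
from loki.st_io import InputError


class TestAugmentPoints:
    def test_constant_embeddings_fall_back_to_spatial_only(self):
        coords = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        ps = augment_points(coords, np.ones((4, 16)))
        assert ps.features.shape[1] == 0
        assert ps.dim == 2

    def test_full_rank_input_gives_four_dimensions(self):
        rng = np.random.default_rng(0)
        ps = augment_points(rng.normal(size=(20, 2)), rng.normal(size=(20, 8)))
        assert ps.dim == 4

    def test_duplicated_coordinates_as_embeddings_correlate_with_space(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(50, 2))
        embs = np.hstack([coords, coords])  # embeddings = coordinates duplicated
        ps = augment_points(coords, embs)
        # each feature column is a rotation of the spatial plane: the PCA
        # scores must be reproducible from the spatial columns by least squares
        beta, *_ = np.linalg.lstsq(ps.spatial, ps.features, rcond=None)
        resid = ps.features - ps.spatial @ beta
        assert np.abs(resid).max() < 1e-8

    def test_shared_basis_keeps_sections_comparable(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(30, 2))
        embs = rng.normal(size=(30, 10))
        src, tgt = augment_pair(coords, embs, coords, embs)
        np.testing.assert_allclose(src.features, tgt.features, atol=1e-12)


class TestInitSigma2:
    def test_hand_evaluated_value(self):
        x = np.array([[0.0, 0.0], [2.0, 0.0]])
        y = np.array([[0.0, 0.0]])
        assert init_sigma2(x, y) == pytest.approx(1.0)

    def test_identical_single_points_floored(self):
        assert init_sigma2(np.zeros((1, 2)), np.zeros((1, 2))) == pytest.approx(1e-12)

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(5, 2)), rng.normal(size=(4, 2))
        assert init_sigma2(3 * x, 3 * y) == pytest.approx(9 * init_sigma2(x, y))


class TestGaussianKernel:
    def test_unit_diagonal_and_known_offdiagonal(self):
        y = np.array([[0.0, 0.0], [2.0, 0.0]])
        g = gaussian_kernel(y, beta=2.0)
        assert g[0, 0] == pytest.approx(1.0)
        assert g[0, 1] == pytest.approx(np.exp(-0.5))

    def test_symmetric_with_entries_in_unit_interval(self):
        rng = np.random.default_rng(4)
        g = gaussian_kernel(rng.normal(size=(10, 2)), beta=1.3)
        np.testing.assert_allclose(g, g.T, atol=1e-15)
        assert (g > 0).all() and (g <= 1).all()


class TestEstep:
    def test_equidistant_sources_split_evenly(self):
        x = np.array([[0.0, 0.0]])
        t = np.array([[1.0, 0.0], [-1.0, 0.0]])
        p = estep_posterior(x, t, sigma2=0.5, w=0.0)
        np.testing.assert_allclose(p[:, 0], [0.5, 0.5])

    def test_columns_sum_to_one_without_outliers(self):
        rng = np.random.default_rng(5)
        p = estep_posterior(rng.normal(size=(7, 2)), rng.normal(size=(4, 2)), 0.3, w=0.0)
        np.testing.assert_allclose(p.sum(axis=0), np.ones(7), atol=1e-12)

    def test_outlier_term_shrinks_far_columns(self):
        x = np.array([[100.0, 100.0], [0.0, 0.0]])
        t = np.array([[0.0, 0.0], [1.0, 0.0]])
        p = estep_posterior(x, t, sigma2=1.0, w=0.5)
        assert p[:, 0].sum() < 1e-6  # far-away target mostly explained as outlier
        assert p[:, 1].sum() < 1.0


def _brute_sigma2(x, t, p):
    """Direct trace evaluation of the variance update."""
    pt1 = p.sum(axis=0)
    p1 = p.sum(axis=1)
    term = (
        np.trace(x.T @ np.diag(pt1) @ x)
        - 2 * np.trace((p @ x).T @ t)
        + np.trace(t.T @ np.diag(p1) @ t)
    )
    return term / (p.sum() * x.shape[1])


class TestMstep:
    def test_perfect_correspondence_drives_sigma_to_zero(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(5, 2))
        x = y.copy()
        g = gaussian_kernel(y, 2.0)
        p = np.eye(5)
        w, t, s2 = mstep_update(x, y, g, p, lam=2.0, sigma2=0.1)
        assert np.abs(w).max() < 1e-6
        assert s2 == pytest.approx(1e-12)

    def test_transform_identity_t_equals_y_plus_gw(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=(6, 2)), rng.normal(size=(5, 2))
        g = gaussian_kernel(y, 1.0)
        p = estep_posterior(x, y, 0.5)
        w, t, _ = mstep_update(x, y, g, p, lam=1.5, sigma2=0.5)
        np.testing.assert_allclose(t, y + g @ w, atol=1e-12)

    def test_sigma2_matches_trace_oracle_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            x, y = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))
            g = gaussian_kernel(y, 1.0)
            p = estep_posterior(x, y, 0.7)
            _, t, s2 = mstep_update(x, y, g, p, lam=2.0, sigma2=0.7)
            assert s2 == pytest.approx(_brute_sigma2(x, t, p), abs=1e-10)

    def test_feature_columns_of_w_are_zero(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        g = gaussian_kernel(y, 2.0)
        p = estep_posterior(x, y, 1.0)
        w, _, _ = mstep_update(x, y, g, p, lam=2.0, sigma2=1.0, n_spatial=2)
        assert np.abs(w[:, 2:]).max() == 0.0


class TestCpdAlign:
    def test_identity_alignment(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(size=(30, 2))
        src = augment_points(coords)
        res = cpd_align(src, augment_points(coords))
        diameter = np.linalg.norm(coords.max(axis=0) - coords.min(axis=0))
        assert np.linalg.norm(res.coordinates - coords, axis=1).mean() < 1e-6 * diameter

    def test_translation_recovered(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(size=(40, 2)) * 10
        shifted = coords + np.array([5.0, 0.0])
        res = align.align_sections(shifted, coords)
        # recovered rigid map applied to the shifted set lands on the original
        np.testing.assert_allclose(
            res.coordinates, coords, atol=1e-2 * np.abs(coords).max()
        )

    def test_rotation_recovered_with_matched_features(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(size=(30, 2)) * 8
        feats = rng.normal(size=(30, 6))
        ang = np.deg2rad(15)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rotated = coords @ rot.T
        res = align.align_sections(rotated, coords, feats, feats)
        nn = np.linalg.norm(res.coordinates - coords, axis=1)
        spacing = np.mean(
            [np.sort(np.linalg.norm(coords - c, axis=1))[1] for c in coords]
        )
        assert nn.mean() < 0.05 * spacing

    def test_sigma2_trace_positive_and_finite(self):
        rng = np.random.default_rng(13)
        coords = rng.normal(size=(25, 2))
        res = cpd_align(augment_points(coords), augment_points(coords))
        trace = np.array(res.sigma2_trace)
        assert np.isfinite(trace).all() and (trace > 0).all()

    def test_rigid_output_is_isometric(self):
        rng = np.random.default_rng(14)
        coords = rng.normal(size=(20, 2)) * 4
        target = coords @ np.array([[0.0, -1.0], [1.0, 0.0]]).T + 3.0
        res = align.align_sections(coords, target)
        d_before = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        d_after = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None], axis=2
        )
        np.testing.assert_allclose(d_before, d_after, atol=1e-9)

    def test_mismatched_dimensionality_rejected(self):
        rng = np.random.default_rng(15)
        a = augment_points(rng.normal(size=(10, 2)), rng.normal(size=(10, 5)))
        b = augment_points(rng.normal(size=(10, 2)))
        with pytest.raises(InputError):
            cpd_align(a, b)


class TestRigidProjection:
    def test_exact_rigid_motion_recovered(self):
        rng = np.random.default_rng(16)
        pts = rng.normal(size=(12, 2))
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = pts @ rot.T + np.array([2.0, -1.0])
        r, t = rigid_projection(pts, moved)
        np.testing.assert_allclose(r, rot, atol=1e-10)
        np.testing.assert_allclose(t, [2.0, -1.0], atol=1e-10)
        assert np.linalg.det(r) == pytest.approx(1.0)


class TestEvaluateAlignment:
    def test_self_alignment_gives_perfect_correlation(self, small_cohort):
        m = small_cohort.spots
        out = evaluate_alignment(m.coords, m, m, top_genes=50)
        assert out["median_pcc"] == pytest.approx(1.0)

    def test_permuted_expression_decorrelates(self, small_cohort):
        m = small_cohort.spots
        rng = np.random.default_rng(0)
        shuffled = m.subset_genes(rng.permutation(m.n_genes))
        shuffled.gene_ids = list(m.gene_ids)  # same symbols, permuted values
        out = evaluate_alignment(m.coords, shuffled, m, top_genes=50)
        assert abs(out["median_pcc"]) < 0.35
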