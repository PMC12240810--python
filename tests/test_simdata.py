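import numpy as np
import pytest

from loki import simdata
from loki.simdata import (
    CohortSpec,
    PerturbSpec,
    add_feature_noise,
    downsample_depth,
    make_pseudo_spots,
    perturb_section,
    simulate_paired_cohort,
)
from loki.st_io import InputError


class TestSimulateCohort:
    def test_bit_reproducible_per_seed(self):
        a = simulate_paired_cohort(CohortSpec(n_spots=30, n_genes=40, seed=5))
        b = simulate_paired_cohort(CohortSpec(n_spots=30, n_genes=40, seed=5))
        np.testing.assert_array_equal(a.spots.to_dense(), b.spots.to_dense())
        np.testing.assert_array_equal(a.features, b.features)
        c = simulate_paired_cohort(CohortSpec(n_spots=30, n_genes=40, seed=6))
        assert not np.array_equal(a.spots.to_dense(), c.spots.to_dense())

    def test_fraction_rows_on_simplex(self, cohort):
        frac = cohort.fractions.to_numpy()
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-9)
        assert (frac >= 0).all()

    def test_noise_free_features_recover_fractions(self):
        spec = CohortSpec(n_spots=25, n_genes=30, feature_noise_sd=0.0, seed=2)
        cohort = simulate_paired_cohort(spec)
        # features = A f exactly; least squares through A must return f
        recovered, *_ = np.linalg.lstsq(
            cohort.feature_map, cohort.features.T, rcond=None
        )
        np.testing.assert_allclose(recovered.T, cohort.fractions.to_numpy(), atol=1e-9)

    def test_negative_binomial_means_match_target(self):
        spec = CohortSpec(n_spots=1000, n_genes=20, n_types=2, seed=3)
        cohort = simulate_paired_cohort(spec)
        counts = cohort.spots.to_dense()  # genes x spots
        depths = counts.sum(axis=0)
        # per-gene expected share of depth given the latent mixtures
        expected = (cohort.fractions.to_numpy() @ cohort.loadings.T).T
        lib = depths / expected.sum(axis=0)
        for g in range(0, 20, 5):
            target = (expected[g] * lib).mean()
            observed = counts[g].mean()
            var = counts[g].var(ddof=1) / counts.shape[1]
            assert abs(observed - target) <= 3 * np.sqrt(var) + 1e-9

    def test_invalid_spec_rejected(self):
        with pytest.raises(InputError):
            CohortSpec(concentration=0.0)


class TestPerturbSection:
    def test_zero_noise_is_identity(self, small_cohort):
        out, truth = perturb_section(small_cohort.spots, PerturbSpec(seed=0))
        np.testing.assert_allclose(out.coords, small_cohort.spots.coords, atol=1e-12)
        np.testing.assert_array_equal(out.to_dense(), small_cohort.spots.to_dense())
        np.testing.assert_allclose(truth["rotation"], np.eye(2), atol=1e-15)

    def test_total_counts_conserved_under_resampling(self, small_cohort):
        spec = PerturbSpec(resample_rate=0.4, seed=1)
        out, _ = perturb_section(small_cohort.spots, spec)
        np.testing.assert_array_equal(
            np.asarray(out.counts.sum(axis=0)).ravel(),
            np.asarray(small_cohort.spots.counts.sum(axis=0)).ravel(),
        )

    def test_inverse_transform_restores_coordinates(self, small_cohort):
        spec = PerturbSpec(rotation_deg=20, translation=(3.0, -2.0), jitter_sd=0.1, seed=2)
        out, truth = perturb_section(small_cohort.spots, spec)
        restored = truth["inverse"](out.coords)
        err = np.linalg.norm(restored - small_cohort.spots.coords, axis=1)
        assert err.mean() < 3 * spec.jitter_sd

    def test_presets_document_noise_levels(self):
        low, high = PerturbSpec.low(), PerturbSpec.high()
        assert low.resample_rate == 0.10 and high.resample_rate == 0.40
        assert low.jitter_sd == 0.25 and high.jitter_sd == 1.0


class TestDownsampleDepth:
    def test_full_depth_is_identity(self, small_cohort):
        m = small_cohort.spots
        median = float(np.median(np.asarray(m.counts.sum(axis=0)).ravel()))
        out = downsample_depth(m, median, seed=0)
        # p = 1: binomial thinning keeps every count
        np.testing.assert_array_equal(out.to_dense(), m.to_dense())

    def test_expected_total_matches_thinning_rate(self, cohort):
        m = cohort.spots
        median = float(np.median(np.asarray(m.counts.sum(axis=0)).ravel()))
        target = median / 4
        out = downsample_depth(m, target, seed=1)
        p = target / median
        total = m.counts.sum()
        observed = out.counts.sum()
        se = np.sqrt(total * p * (1 - p))
        assert abs(observed - p * total) <= 3 * se

    def test_ranks_preserved_in_expectation(self, cohort):
        m = cohort.spots
        median = float(np.median(np.asarray(m.counts.sum(axis=0)).ravel()))
        out = downsample_depth(m, median / 5, seed=2)
        # pseudo-bulk gene ranking is stable under uniform thinning
        before = np.asarray(m.counts.sum(axis=1)).ravel()
        after = np.asarray(out.counts.sum(axis=1)).ravel()
        from loki.metrics import pearson

        assert pearson(before, after) > 0.99

    def test_excessive_target_rejected(self, small_cohort):
        with pytest.raises(InputError):
            downsample_depth(small_cohort.spots, 1e9)


class TestPseudoSpots:
    def test_colocated_cells_average(self):
        coords = np.array([[0.05, 0.0], [-0.05, 0.0]])
        expr = np.array([[2.0, 0.0], [0.0, 2.0]])
        spots, assignment = make_pseudo_spots(coords, expr, ["g1", "g2"], spacing=1.0)
        assert spots.n_spots == 1
        np.testing.assert_allclose(spots.to_dense().ravel(), [1.0, 1.0])
        assert (assignment >= 0).all()

    def test_one_cell_per_spot_passes_profiles_through(self):
        coords = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
        expr = np.arange(9.0).reshape(3, 3)
        spots, _ = make_pseudo_spots(coords, expr, ["a", "b", "c"], spacing=5.0)
        assert spots.n_spots == 3
        assert sorted(spots.to_dense().T.sum(axis=1).tolist()) == sorted(
            expr.sum(axis=1).tolist()
        )

    def test_assignment_matches_nearest_center_oracle(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 10, size=(50, 2))
        expr = rng.random((50, 4))
        spots, assignment = make_pseudo_spots(coords, expr, list("wxyz"), spacing=2.0)
        for i, a in enumerate(assignment):
            if a < 0:
                continue
            d = np.linalg.norm(spots.coords - coords[i], axis=1)
            assert d[a] == pytest.approx(d.min())

    def test_no_cell_in_any_spot_rejected(self):
        # grid origin is the elementwise coordinate minimum (0, 0); both
        # cells sit 1 unit from every center, beyond the 0.25 radius
        with pytest.raises(InputError):
            make_pseudo_spots(
                np.array([[0.0, 1.0], [1.0, 0.0]]),
                np.ones((2, 1)),
                ["g"],
                spacing=2.0,
                diameter=0.5,
            )


class TestFeatureNoise:
    def test_zero_sd_identity(self):
        x = np.random.default_rng(4).random((5, 3))
        np.testing.assert_array_equal(add_feature_noise(x, 0.0), x)

    def test_noise_variance_matches_sd(self):
        x = np.zeros((200, 50))
        sd = 0.7
        noisy = add_feature_noise(x, sd, seed=5)
        n = noisy.size
        se_var = sd**2 * np.sqrt(2 / (n - 1))
        assert abs(noisy.var() - sd**2) <= 3 * se_var

    def test_similarity_decays_with_noise(self):
        rng = np.random.default_rng(6)
        x = rng.random((100, 20))
        sims = []
        for sd in (0.1, 0.5, 2.0, 8.0):
            noisy = add_feature_noise(x, sd, seed=7)
            cos = np.sum(x * noisy, axis=1) / (
                np.linalg.norm(x, axis=1) * np.linalg.norm(noisy, axis=1)
            )
            sims.append(cos.mean())
        assert all(a > b for a, b in zip(sims, sims[1:]))


def test_paired_cohort_has_cross_modal_signal(cohort):
    """Matched (image, text) spot pairs are more similar than mismatched ones
    after adapter alignment — the property contrastive training amplifies."""
    from loki.encoder import EncoderConfig, ImageEncoder, TextEncoder, finetune_adapters
    from loki.sentences import build_corpus

    cfg = EncoderConfig(seed=7)
    text = TextEncoder(cfg).encode_many(
        build_corpus(cohort.spots, deduplicate=False).sentences
    )
    image = ImageEncoder(cfg).encode_many(cohort.features)
    pair = finetune_adapters(image, text, epochs=5, cfg=cfg)
    a = pair.apply_image(image)
    b = pair.apply_text(text)
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    sims = a @ b.T
    matched = np.diag(sims).mean()
    mismatched = (sims.sum() - np.trace(sims)) / (sims.size - len(sims))
    assert matched > mismatched
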