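"""Grain model, analytic moments, Monte-Carlo covariance, posterior,
and the image-based validation of the moment constants."""

import numpy as np
import pytest
from scipy import stats

from ibrcluster.granulometry import (GrainModel, GranularEffectiveModel,
                                     GranularPriorGrid, PRIMITIVE_SWAP,
                                     asymptotic_mean, beta_scaling,
                                     estimate_feature_covariance,
                                     gamma_moments, granular_label_posterior,
                                     moment_matrix, pattern_spectrum_moment,
                                     rasterize_rod, rasterize_triangle,
                                     sample_features, size_distribution)
from ibrcluster.partitions import SizeSpec
from ibrcluster.robust import label_posterior


class TestMomentMatrix:
    def test_printed_constants(self):
        M = moment_matrix()
        assert M[0, 0] == pytest.approx(2 * 3 ** -0.75)
        assert M[1, 0] == pytest.approx(4 * 3 ** -1.25)
        assert M[0, 1] == pytest.approx(5 ** 0.5)
        assert M[1, 1] == pytest.approx(5 ** -0.5)
        assert M[2, 2] == pytest.approx(0.5 * 3 ** 0.5)
        assert M[3, 2] == pytest.approx(2 * 3 ** -0.5)
        assert M[2, 3] == pytest.approx(5.0)
        assert M[3, 3] == pytest.approx(0.2)

    def test_block_zero_structure_orders_do_not_mix(self):
        M = moment_matrix()
        assert np.all(M[:2, 2:] == 0.0) and np.all(M[2:, :2] == 0.0)
        assert np.all(M[M != 0] > 0)
        assert np.linalg.matrix_rank(M) == 4  # features x = M^-1 z exist


class TestGammaMoments:
    def test_low_orders(self):
        assert gamma_moments(2.5, 1) == pytest.approx(2.5)
        assert gamma_moments(2.5, 2) == pytest.approx(2.5 * 3.5)

    def test_matches_log_gamma_ratio(self):
        from scipy.special import gammaln
        got = gamma_moments(1.95, 3)
        want = np.exp(gammaln(1.95 + 3) - gammaln(1.95))
        assert got == pytest.approx(want, rel=1e-12)
        assert got == pytest.approx(1.95 * 2.95 * 3.95, rel=1e-12)

    def test_invalid_shape(self):
        with pytest.raises(ValueError):
            gamma_moments(-1.0, 1)


class TestSampleFeatures:
    def test_positive_components_and_shape(self, rng):
        x = sample_features(GrainModel(), rng, size=50)
        assert x.shape == (50, 4)
        assert np.all(x > 0)

    def test_monte_carlo_mean_matches_asymptotic(self, rng):
        m = GrainModel()
        draws = sample_features(m, rng, size=10_000)
        target = asymptotic_mean(m.proportions, m.beta, m.alphas)
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - target) < 3 * se)

    def test_beta_scaling_is_exact_pathwise(self):
        """Scaling beta by s multiplies the k=1 components by s and the
        k=2 components by s^2, draw by draw."""
        m1 = GrainModel(beta=1.0)
        m2 = GrainModel(beta=2.0)
        a = sample_features(m1, np.random.default_rng(9), size=100)
        b = sample_features(m2, np.random.default_rng(9), size=100)
        np.testing.assert_allclose(b, a * np.array([2, 2, 4, 4]), rtol=1e-12)

    def test_fixed_counts_split(self, rng):
        x = sample_features(GrainModel(proportions=(0.3, 0.7), n_grains=10),
                            rng, size=5, fixed_counts=True)
        assert np.all(x > 0)

    def test_marginals_approach_gaussian_as_grains_grow(self, rng):
        """Supports the asymptotic normality the posterior assumes: the
        marginal skewness decays with the grain count (roughly 1/sqrt(N);
        the second-order components keep visible skew ~1 even at N=1000
        because the r^4 sums are heavy-tailed)."""
        few = sample_features(GrainModel(n_grains=100), rng, size=4000)
        many = sample_features(GrainModel(n_grains=1000), rng, size=4000)
        s_few = np.abs(stats.skew(few, axis=0))
        s_many = np.abs(stats.skew(many, axis=0))
        assert np.all(s_many < s_few)
        assert np.all(s_many < 1.5)


class TestAsymptoticMean:
    def test_degenerate_proportion(self):
        v = asymptotic_mean((0.0, 1.0), 2.0, (1.95, 1.97))
        assert v[0] == 0.0 and v[2] == 0.0 and v[1] > 0 and v[3] > 0

    def test_symmetry_under_equal_shapes(self):
        v = asymptotic_mean((0.5, 0.5), 2.0, (1.95, 1.95))
        assert v[0] == pytest.approx(v[1]) and v[2] == pytest.approx(v[3])


class TestFeatureCovariance:
    def test_symmetric_psd_and_cached(self, rng):
        m = GrainModel(n_grains=200)
        c1 = estimate_feature_covariance(m, reps=2000, seed=3)
        c2 = estimate_feature_covariance(m, reps=2000, seed=3)
        assert c1 is c2  # cache hit
        np.testing.assert_array_equal(c1, c1.T)
        assert np.all(np.linalg.eigvalsh(c1) > 0)

    def test_one_over_n_scaling(self):
        """Halving the grain count roughly doubles every covariance entry."""
        big = estimate_feature_covariance(GrainModel(n_grains=200),
                                          reps=20_000, seed=4)
        small = estimate_feature_covariance(GrainModel(n_grains=100),
                                            reps=20_000, seed=5)
        ratio = np.diag(small) / np.diag(big)
        assert np.all(ratio > 1.8) and np.all(ratio < 2.2)

    def test_block_beta_scaling(self):
        """Entries for moment orders (k, k') scale as beta^(k+k')."""
        c1 = estimate_feature_covariance(GrainModel(beta=1.0, n_grains=200),
                                         reps=5000, seed=6)
        c2 = estimate_feature_covariance(GrainModel(beta=2.0, n_grains=200),
                                         reps=5000, seed=6)
        D = beta_scaling(2.0)
        np.testing.assert_allclose(c2, D @ c1 @ D, rtol=1e-10)

    def test_low_rep_warning(self):
        with pytest.warns(UserWarning):
            estimate_feature_covariance(GrainModel(n_grains=50), reps=50,
                                        seed=7)


@pytest.fixture(scope="module")
def small_model():
    grid = GranularPriorGrid(rho_values=tuple(np.linspace(0.45, 0.55, 5)),
                             theta_values=tuple(np.linspace(1.75, 2.0, 3)),
                             n_grains=200)
    return GranularEffectiveModel(grid, SizeSpec.fixed((3, 3)),
                                  cov_reps=2000, cov_seed=1)


class TestGranularPosterior:
    def test_normalizes(self, small_model, rng):
        X = sample_features(GrainModel(n_grains=200), rng, size=6)
        post = label_posterior(X, small_model)
        assert post.probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_class_swap_symmetry(self, small_model, rng):
        """Swapping the components of every feature vector by the
        primitive permutation swaps the roles of the two classes, leaving
        partition probabilities unchanged (the rho grid is symmetric
        about 1/2 and theta maps to beta_total - theta)."""
        from ibrcluster.robust import partition_posterior
        X = sample_features(GrainModel(n_grains=200), rng, size=6)
        d1 = partition_posterior(X, small_model)
        Xs = X @ PRIMITIVE_SWAP.T
        d2 = partition_posterior(Xs, small_model)
        assert d1.partitions == d2.partitions
        np.testing.assert_allclose(d1.probs, d2.probs, atol=1e-8)

    def test_single_grid_point_reduces_to_plain_gaussian(self, rng):
        """A 1x1 grid is a plain Gaussian label posterior."""
        grid = GranularPriorGrid(rho_values=(0.5,), theta_values=(1.875,),
                                 n_grains=200)
        model = GranularEffectiveModel(grid, SizeSpec.fixed((3, 3)),
                                       cov_reps=2000, cov_seed=2)
        X = sample_features(GrainModel(n_grains=200), rng, size=6)
        post = label_posterior(X, model)
        # check a hand-rolled plain-Gaussian computation agrees
        from scipy.stats import multivariate_normal
        lab = post.labelings[0]
        logw = 0.0
        for y in (1, 2):
            b, a, beta = grid.class_params(0.5, 1.875, y)
            mean = asymptotic_mean(b, beta, a)
            base = estimate_feature_covariance(
                GrainModel(alphas=grid.alphas_class1, beta=1.0,
                           proportions=(0.5, 0.5), n_grains=200),
                reps=2000,
                seed=int(np.random.SeedSequence(2).generate_state(1)[0]
                         & 0x7FFFFFFF))
            D = beta_scaling(beta)
            S = base if y == 1 else PRIMITIVE_SWAP @ base @ PRIMITIVE_SWAP
            cov = D @ S @ D
            pts = X[lab == y]
            logw += multivariate_normal(mean, cov).logpdf(pts).sum()
        assert model.log_label_weight(X, lab) == pytest.approx(logw, rel=1e-9)

    def test_granular_label_posterior_function(self, rng):
        grid = GranularPriorGrid(rho_values=(0.48, 0.52),
                                 theta_values=(1.8,), n_grains=200)
        X = sample_features(GrainModel(n_grains=200), rng, size=4)
        post = granular_label_posterior(X, grid, SizeSpec.fixed((2, 2)),
                                        cov_reps=1000, cov_seed=3)
        assert post.probs.shape == (6,)
        assert post.probs.sum() == pytest.approx(1.0, abs=1e-10)


class TestPatternSpectrum:
    def test_size_distribution_non_increasing(self):
        img = rasterize_triangle(30.0)
        omega = size_distribution(img, "vertical")
        assert np.all(np.diff(omega) <= 0)
        assert omega[-1] == 0.0

    def test_triangle_first_moment_matches_constant(self):
        """Rasterized unit-area triangle scaled by r under a vertical
        line: first pattern-spectrum moment ~ 2*3^(-3/4) r."""
        r = 48.0
        got = pattern_spectrum_moment(rasterize_triangle(r), "vertical", 1)
        want = 2 * 3 ** -0.75 * r
        assert got == pytest.approx(want, rel=0.05)

    def test_rod_first_moment_matches_constant(self):
        """Rasterized 1:5 rod under a vertical line: first moment ~ 5^(1/2) r."""
        r = 40.0
        got = pattern_spectrum_moment(rasterize_rod(r), "vertical", 1)
        assert got == pytest.approx(5 ** 0.5 * r, rel=0.05)

    def test_rod_horizontal_first_moment(self):
        r = 60.0
        got = pattern_spectrum_moment(rasterize_rod(r), "horizontal", 1)
        assert got == pytest.approx(5 ** -0.5 * r, rel=0.05)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            pattern_spectrum_moment(np.zeros((5, 5), dtype=bool))
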