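"""scikit-learn-style clustering estimators.

Thin orchestration over the library layer: each estimator validates its
input, builds the corresponding probabilistic model, solves for the
optimal (or approximate) partition on ``fit``, and exposes ``labels_``
plus model-specific fitted attributes. All compose with sklearn
pipelines and ``clone``/``get_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .gaussian import GaussianRLPPSpec
from .granulometry import GranularEffectiveModel, GranularPriorGrid
from .partitions import DEFAULT_GUARD, SizeSpec
from .robust import DiscreteUncertaintyClass, ExactIBREngine
from .search import SearchConfig, approx_ibr


def _default_sizes(n: int, k: int) -> tuple:
    base = [n // k] * k
    for j in range(n % k):
        base[j] += 1
    return tuple(base)


class _ExactOrApproxMixin:
    """Shared fit core: exact Bayes partition within the enumeration
    guard, MAP search beyond it."""

    def _solve(self, X, model, rng):
        n = X.shape[0]
        use_approx = (self.approx is True
                      or (self.approx == "auto" and n > self.max_exact_n))
        if use_approx:
            config = SearchConfig(subset_size=self.subset_size,
                                  restarts=self.restarts)
            part = approx_ibr(X, model, config, rng,
                              guard=self.max_exact_n)
            self.partition_ = part
            self.risk_ = None
            self.posterior_ = None
        else:
            if n > self.max_exact_n:
                raise ValueError(
                    f"exact solver refused for n={n} > "
                    f"max_exact_n={self.max_exact_n}; set approx=True")
            engine = ExactIBREngine(n, model.label_prior,
                                    guard=self.max_exact_n)
            part, risk, dist = engine.solve(X, model)
            self.partition_ = part
            self.risk_ = risk
            self.posterior_ = dist
        self.labels_ = self.partition_.label_vector()
        return self


class GaussianIBRClusterer(_ExactOrApproxMixin, ClusterMixin, BaseEstimator):
    """IBR clusterer for the Gaussian uncertainty class.

    The state of nature is the per-cluster covariance (inverse-Wishart
    with ``kappa`` degrees of freedom and scale ``psi``); given the
    state, cluster means are Gaussian around ``m`` with covariance
    ``Sigma/nu``. The effective process collapses analytically into the
    normal-inverse-Wishart form, so the IBR partition is the Bayes
    partition under that closed-form posterior (exact for small n, the
    seeded MAP search otherwise).

    Parameters default to the benchmark setting: kappa = d+2, psi = I,
    nu = 1, m = 0, equal fixed cluster sizes.
    """

    def __init__(self, n_clusters: int = 2, sizes=None, kappa=None,
                 nu: float = 1.0, psi=None, m=None,
                 max_exact_n: int = DEFAULT_GUARD, approx="auto",
                 subset_size: int = 10, restarts: int = 10,
                 random_state=None):
        self.n_clusters = n_clusters
        self.sizes = sizes
        self.kappa = kappa
        self.nu = nu
        self.psi = psi
        self.m = m
        self.max_exact_n = max_exact_n
        self.approx = approx
        self.subset_size = subset_size
        self.restarts = restarts
        self.random_state = random_state

    def _build_spec(self, X) -> GaussianRLPPSpec:
        n, d = X.shape
        sizes = self.sizes if self.sizes is not None \
            else _default_sizes(n, self.n_clusters)
        prior = SizeSpec.fixed(sizes)
        if prior.n != n:
            raise ValueError("cluster sizes must sum to the number of points")
        return GaussianRLPPSpec.symmetric(
            d, prior, kappa=self.kappa, nu=self.nu, psi=self.psi, m=self.m)

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        rng = np.random.default_rng(self.random_state)
        self.spec_ = self._build_spec(X)
        return self._solve(X, self.spec_, rng)


class MixtureIBRClusterer(_ExactOrApproxMixin, ClusterMixin, BaseEstimator):
    """IBR clusterer over an explicit finite uncertainty class of
    separable RLPP states with prior weights."""

    def __init__(self, states=None, weights=None,
                 max_exact_n: int = DEFAULT_GUARD, approx="auto",
                 subset_size: int = 10, restarts: int = 10,
                 random_state=None):
        self.states = states
        self.weights = weights
        self.max_exact_n = max_exact_n
        self.approx = approx
        self.subset_size = subset_size
        self.restarts = restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        if not self.states:
            raise ValueError("states must be a nonempty list of RLPP specs")
        weights = self.weights
        if weights is None:
            weights = np.full(len(self.states), 1.0 / len(self.states))
        X = check_array(X, ensure_min_samples=2)
        rng = np.random.default_rng(self.random_state)
        self.uncertainty_ = DiscreteUncertaintyClass(tuple(self.states),
                                                     np.asarray(weights))
        return self._solve(X, self.uncertainty_, rng)


class GranularIBRClusterer(ClusterMixin, BaseEstimator):
    """IBR clusterer for granulometric grain features.

    Points are 4-d feature vectors of grain images; the uncertainty
    class mixes a discrete grid over the class-1 triangle proportion rho
    and the scale state theta, with Gaussian class-conditional features
    (analytic asymptotic means, cached Monte-Carlo covariances).
    """

    def __init__(self, sizes=(5, 5), rho_grid: int = 500,
                 theta_grid: int = 10, cov_reps: int = 10_000,
                 cov_seed: int = 0, n_grains: int = 1000,
                 max_exact_n: int = DEFAULT_GUARD, model=None):
        self.sizes = sizes
        self.rho_grid = rho_grid
        self.theta_grid = theta_grid
        self.cov_reps = cov_reps
        self.cov_seed = cov_seed
        self.n_grains = n_grains
        self.max_exact_n = max_exact_n
        self.model = model

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        if X.shape[1] != 4:
            raise ValueError("granular features are 4-dimensional")
        prior = SizeSpec.fixed(self.sizes)
        if self.model is not None:
            model = self.model.with_label_prior(prior)
        else:
            grid = GranularPriorGrid(
                rho_values=tuple(np.linspace(0.45, 0.55, self.rho_grid)),
                theta_values=tuple(np.linspace(1.75, 2.0, self.theta_grid)),
                n_grains=self.n_grains)
            model = GranularEffectiveModel(grid, prior,
                                           cov_reps=self.cov_reps,
                                           cov_seed=self.cov_seed)
        self.model_ = model
        engine = ExactIBREngine(X.shape[0], prior, guard=self.max_exact_n)
        part, risk, dist = engine.solve(X, model)
        self.partition_ = part
        self.risk_ = risk
        self.posterior_ = dist
        self.labels_ = part.label_vector()
        return self


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means (Bezdek), fuzzifier ``m``; hard labels by maximum
    membership."""

    def __init__(self, n_clusters: int = 2, m: float = 2.0,
                 max_iter: int = 300, tol: float = 1e-5,
                 random_state=None):
        self.n_clusters = n_clusters
        self.m = m
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=self.n_clusters)
        rng = np.random.default_rng(self.random_state)
        n, _ = X.shape
        k, m = self.n_clusters, self.m
        u = rng.dirichlet(np.ones(k), size=n)  # (n, k) memberships
        for it in range(self.max_iter):
            um = u ** m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            d2 = np.maximum(d2, 1e-12)
            inv = d2 ** (-1.0 / (m - 1.0))
            new_u = inv / inv.sum(axis=1, keepdims=True)
            shift = np.abs(new_u - u).max()
            u = new_u
            if shift < self.tol:
                break
        self.n_iter_ = it + 1
        self.cluster_centers_ = centers
        self.membership_ = u
        self.labels_ = u.argmax(axis=1) + 1
        return self


class RandomClusterer(ClusterMixin, BaseEstimator):
    """Reference clusterer producing random partitions ('equal-sizes' or
    'iid-labels')."""

    def __init__(self, n_clusters: int = 2, mode: str = "iid-labels",
                 random_state=None):
        self.n_clusters = n_clusters
        self.mode = mode
        self.random_state = random_state

    def fit(self, X, y=None):
        from .baselines import random_partition
        X = check_array(X)
        rng = np.random.default_rng(self.random_state)
        self.labels_ = random_partition(X.shape[0], self.mode,
                                        self.n_clusters, rng)
        return self


def predict_partition(estimator):
    """Fitted partition of any of the clusterers above."""
    check_is_fitted(estimator, "labels_")
    from .partitions import canonicalize
    return canonicalize(estimator.labels_)
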