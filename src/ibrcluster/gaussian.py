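"""Separable Gaussian random labeled point processes.

Clusters are Gaussian with random parameters. Two parameter regimes are
used:

* :class:`GaussianRLPPSpec` — per-label normal-inverse-Wishart (NIW)
  priors: covariance ``Sigma_y ~ IW(kappa_y, Psi_y)`` and mean
  ``mu_y | Sigma_y ~ N(m_y, Sigma_y/nu_y)``. The label-function posterior
  is available in closed form through the NIW marginal likelihood. This
  is also the *effective* process of the uncertainty class whose state is
  the covariance: the inverse-Wishart state prior collapses analytically
  into the NIW form.
* :class:`FixedCovGaussianState` — a single state of that uncertainty
  class: covariances fixed, only the means random.

All log-weights are exact log marginal likelihoods (no dropped
constants), so states with different hyperparameters can be mixed into
one effective process without corrupting the mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import multigammaln
from scipy.stats import invwishart

from .partitions import SizeSpec, _as_labels

_LOG_PI = float(np.log(np.pi))
_LOG_2PI = float(np.log(2.0 * np.pi))


class ConditioningError(RuntimeError):
    """A posterior scatter matrix was not numerically positive-definite."""


@dataclass(frozen=True)
class NIWParams:
    """Normal-inverse-Wishart hyperparameters for one label.

    ``m``: prior mean location; ``nu`` > 0: mean-precision scaling;
    ``kappa`` > d-1: inverse-Wishart degrees of freedom; ``psi``:
    symmetric positive-definite scale matrix. The implied expected
    covariance is ``psi/(kappa-d-1)`` for kappa > d+1.
    """

    m: np.ndarray
    nu: float
    kappa: float
    psi: np.ndarray

    def __post_init__(self):
        m = np.atleast_1d(np.asarray(self.m, dtype=float))
        psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        d = m.size
        if psi.shape != (d, d):
            raise ValueError("psi must be d x d")
        if not np.allclose(psi, psi.T):
            raise ValueError("psi must be symmetric")
        try:
            np.linalg.cholesky(psi)
        except np.linalg.LinAlgError as exc:
            raise ValueError("psi must be positive-definite") from exc
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.kappa <= d - 1:
            raise ValueError("kappa must exceed d - 1")
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "nu", float(self.nu))
        object.__setattr__(self, "kappa", float(self.kappa))

    @property
    def d(self) -> int:
        return self.m.size


def cluster_scatter(points: np.ndarray, prior: NIWParams) -> np.ndarray:
    """Posterior scatter update ``Psi*_y`` for one cluster.

    ``(n_y-1) * sample_cov + nu*n_y/(nu+n_y) * (mean - m)(mean - m)^T``
    for n_y >= 2; the rank-one mean term alone for n_y = 1; the zero
    matrix for an empty cluster. Always symmetric positive-semidefinite.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = prior.d
    if pts.size == 0:
        return np.zeros((d, d))
    if pts.shape[1] != d:
        raise ValueError("point dimension does not match prior")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite points")
    ny = pts.shape[0]
    mean = pts.mean(axis=0)
    dev = mean - prior.m
    mean_term = (prior.nu * ny / (prior.nu + ny)) * np.outer(dev, dev)
    if ny == 1:
        return mean_term
    centered = pts - mean
    return centered.T @ centered + mean_term


def _logdet_chol(a: np.ndarray, what: str) -> float:
    try:
        chol = np.linalg.cholesky(a)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(
            f"{what} is not numerically positive-definite") from exc
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


def _log_niw_marginal(points: np.ndarray, prior: NIWParams) -> float:
    """Exact log marginal likelihood of a cluster under its NIW prior."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ny, d = (0, prior.d) if pts.size == 0 else pts.shape
    if ny == 0:
        return 0.0
    scatter = cluster_scatter(pts, prior)
    ld_post = _logdet_chol(prior.psi + scatter, "psi + scatter")
    ld_prior = _logdet_chol(prior.psi, "psi")
    return (-0.5 * ny * d * _LOG_PI
            + multigammaln(0.5 * (prior.kappa + ny), d)
            - multigammaln(0.5 * prior.kappa, d)
            + 0.5 * prior.kappa * ld_prior
            - 0.5 * (prior.kappa + ny) * ld_post
            + 0.5 * d * (np.log(prior.nu) - np.log(prior.nu + ny)))


@dataclass(frozen=True)
class GaussianRLPPSpec:
    """Separable Gaussian RLPP with per-label NIW priors."""

    niw: tuple
    label_prior: SizeSpec

    def __post_init__(self):
        niw = tuple(self.niw)
        if len(niw) != self.label_prior.n_labels:
            raise ValueError("one NIW prior per label required")
        d = niw[0].d
        if any(p.d != d for p in niw):
            raise ValueError("inconsistent dimension across labels")
        object.__setattr__(self, "niw", niw)

    @classmethod
    def symmetric(cls, d: int, label_prior: SizeSpec, kappa: float | None = None,
                  nu: float = 1.0, psi: np.ndarray | None = None,
                  m: np.ndarray | None = None) -> "GaussianRLPPSpec":
        """Identical hyperparameters for every label (the benchmark default:
        kappa = d+2, Psi = I, nu = 1, m = 0)."""
        kappa = float(d + 2) if kappa is None else float(kappa)
        psi = np.eye(d) if psi is None else np.asarray(psi, dtype=float)
        m = np.zeros(d) if m is None else np.asarray(m, dtype=float)
        p = NIWParams(m=m, nu=nu, kappa=kappa, psi=psi)
        return cls(niw=(p,) * label_prior.n_labels, label_prior=label_prior)

    @property
    def d(self) -> int:
        return self.niw[0].d

    @property
    def n_labels(self) -> int:
        return self.label_prior.n_labels

    def with_label_prior(self, spec: SizeSpec) -> "GaussianRLPPSpec":
        return replace(self, label_prior=spec)

    def log_label_weight(self, X: np.ndarray, labels) -> float:
        """Log posterior weight of a label function (exact up to the
        label-prior normalizer, constant on the support)."""
        labels = _as_labels(labels)
        lp = self.label_prior.log_prior(labels)
        if lp == -np.inf:
            return -np.inf
        X = np.atleast_2d(np.asarray(X, dtype=float))
        total = lp
        for y in range(1, self.n_labels + 1):
            total += _log_niw_marginal(X[labels == y], self.niw[y - 1])
        return float(total)

    # -- sampling -----------------------------------------------------
    def sample_state(self, rng: np.random.Generator) -> "FixedCovGaussianState":
        """Draw the state of nature: one covariance per label from its
        inverse-Wishart prior."""
        sigmas = []
        for p in self.niw:
            s = invwishart(df=p.kappa, scale=p.psi).rvs(random_state=rng)
            sigmas.append(np.atleast_2d(np.asarray(s, dtype=float)))
        return FixedCovGaussianState(
            sigmas=tuple(sigmas),
            means=tuple(p.m for p in self.niw),
            nus=tuple(p.nu for p in self.niw),
            label_prior=self.label_prior)

    def sample(self, rng: np.random.Generator):
        """Draw (point set, true label function): state, then means, then
        points; labels uniformly permuted over the prior support."""
        state = self.sample_state(rng)
        X, labels = state.sample(rng)
        return X, labels, state


@dataclass(frozen=True)
class FixedCovGaussianState:
    """One state of the Gaussian uncertainty class: fixed covariances,
    Gaussian random means ``mu_y ~ N(m_y, Sigma_y/nu_y)``."""

    sigmas: tuple
    means: tuple
    nus: tuple
    label_prior: SizeSpec

    @property
    def d(self) -> int:
        return np.atleast_2d(self.sigmas[0]).shape[0]

    @property
    def n_labels(self) -> int:
        return self.label_prior.n_labels

    def with_label_prior(self, spec: SizeSpec) -> "FixedCovGaussianState":
        return replace(self, label_prior=spec)

    def log_label_weight(self, X: np.ndarray, labels) -> float:
        labels = _as_labels(labels)
        lp = self.label_prior.log_prior(labels)
        if lp == -np.inf:
            return -np.inf
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = self.d
        total = lp
        for y in range(1, self.n_labels + 1):
            pts = X[labels == y]
            ny = pts.shape[0]
            if ny == 0:
                continue
            sigma = np.atleast_2d(self.sigmas[y - 1])
            nu = self.nus[y - 1]
            m = np.atleast_1d(self.means[y - 1])
            prior = NIWParams(m=m, nu=nu, kappa=float(d + 1), psi=sigma)
            scatter = cluster_scatter(pts, prior)
            chol = np.linalg.cholesky(sigma)
            ld = 2.0 * float(np.sum(np.log(np.diag(chol))))
            sol = np.linalg.solve(sigma, scatter)
            total += (-0.5 * ny * d * _LOG_2PI - 0.5 * ny * ld
                      + 0.5 * d * (np.log(nu) - np.log(nu + ny))
                      - 0.5 * float(np.trace(sol)))
        return float(total)

    def sample(self, rng: np.random.Generator):
        """Draw (points, labels) from this state."""
        spec = self.label_prior
        if not spec.is_fixed:
            raise ValueError("sampling requires a fixed-size label prior")
        n = spec.n
        labels = rng.permutation(
            np.repeat(np.arange(1, spec.n_labels + 1), spec.sizes))
        d = self.d
        X = np.empty((n, d))
        for y in range(1, spec.n_labels + 1):
            sigma = np.atleast_2d(self.sigmas[y - 1])
            mu = rng.multivariate_normal(
                np.atleast_1d(self.means[y - 1]), sigma / self.nus[y - 1])
            idx = np.flatnonzero(labels == y)
            X[idx] = rng.multivariate_normal(mu, sigma, size=idx.size)
        return X, labels


def sample_rlpp(spec: GaussianRLPPSpec, rng: np.random.Generator):
    """Convenience wrapper: draw (point set, label function) from the full
    hierarchy (covariances, means, points)."""
    X, labels, _ = spec.sample(rng)
    return X, labels


def label_posterior(X: np.ndarray, spec: GaussianRLPPSpec, guard: int = 22):
    """Normalized posterior over label functions (closed form, log-sum-exp).

    Returns the generic :class:`~ibrcluster.robust.LabelPosterior`.
    """
    from .robust import label_posterior as _generic
    return _generic(X, spec, guard=guard)


def partition_posterior(X: np.ndarray, spec: GaussianRLPPSpec, guard: int = 22):
    """Posterior over partitions: label-function posterior aggregated over
    each partition's inducing labelings."""
    from .robust import partition_posterior as _generic
    return _generic(X, spec, guard=guard)
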