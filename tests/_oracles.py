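"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: brute-force
enumeration over inducing label functions for the natural cost, and
direct numerical quadrature of the parameter integrals for the Gaussian
marginal likelihoods.
"""

import numpy as np
from scipy import integrate
from scipy.stats import invgamma

from ibrcluster.cost import label_mismatch
from ibrcluster.partitions import inducing_label_functions


def brute_force_natural_cost(p, q, l):
    """Minimum label mismatch over all pairs of inducing label functions."""
    best = 1.0
    for phi in inducing_label_functions(p, l):
        for psi in inducing_label_functions(q, l):
            best = min(best, label_mismatch(phi, psi))
    return best


def brute_force_cluster_mismatch(phi, p, l):
    """Minimum label mismatch between phi and the labelings inducing p."""
    return min(label_mismatch(phi, psi)
               for psi in inducing_label_functions(p, l))


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)


def log_marginal_niw_quad(x, m, nu, kappa, psi):
    """log of the 1-d cluster marginal likelihood by 2-d quadrature over
    (mu, log sigma^2) against the normal-inverse-Wishart density.

    Inner mu integral: 64-node Gauss-Hermite with nodes centered and
    scaled from the data (the integrand is Gaussian-shaped in mu at each
    variance, so the rule is effectively exact); outer integral over
    s = log sigma^2: adaptive quadrature.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    n = x.size
    if n == 0:
        return 0.0
    center = (x.sum() + nu * m) / (n + nu)

    def log_integrand(mu, s):
        sig2 = np.exp(s)
        ll = -0.5 * n * np.log(2 * np.pi * sig2) \
            - 0.5 * np.sum((x[:, None] - mu) ** 2, axis=0) / sig2
        lmu = -0.5 * np.log(2 * np.pi * sig2 / nu) \
            - 0.5 * nu * (mu - m) ** 2 / sig2
        lsig = invgamma.logpdf(sig2, a=kappa / 2.0, scale=psi / 2.0)
        return ll + lmu + lsig + s  # + s: Jacobian of sigma^2 = e^s

    ss = np.linspace(-12, 8, 81)
    shift = max(float(log_integrand(np.array([center]), s)[0]) for s in ss)

    def inner(s):
        h = np.sqrt(np.exp(s) / (n + nu))
        mus = center + np.sqrt(2.0) * h * _GH_NODES
        vals = np.exp(log_integrand(mus, s) - shift + _GH_NODES ** 2)
        return float(np.sqrt(2.0) * h * np.sum(_GH_WEIGHTS * vals))

    val, _ = integrate.quad(inner, -16.0, 12.0, epsabs=1e-13, epsrel=1e-11,
                            limit=400)
    return np.log(val) + shift


def log_weight_niw_quad(X, labels, m, nu, kappa, psi):
    """Quadrature log weight of a labeling: sum of per-cluster marginals."""
    X = np.asarray(X, dtype=float).ravel()
    labels = np.asarray(labels)
    total = 0.0
    for y in np.unique(labels):
        total += log_marginal_niw_quad(X[labels == y], m, nu, kappa, psi)
    return total


def log_marginal_fixedcov_quad(x, m, nu, sigma2):
    """log of the 1-d cluster marginal with fixed variance, integrating
    only the Gaussian mean prior."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    n = x.size
    if n == 0:
        return 0.0

    def log_integrand(mu):
        ll = -0.5 * n * np.log(2 * np.pi * sigma2) \
            - 0.5 * np.sum((x - mu) ** 2) / sigma2
        lmu = -0.5 * np.log(2 * np.pi * sigma2 / nu) \
            - 0.5 * nu * (mu - m) ** 2 / sigma2
        return ll + lmu

    shift = log_integrand(x.mean())
    val, _ = integrate.quad(lambda mu: np.exp(log_integrand(mu) - shift),
                            x.min() - 40, x.max() + 40,
                            epsabs=1e-13, epsrel=1e-11)
    return np.log(val) + shift
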