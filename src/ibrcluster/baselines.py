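"""Classical comparison clusterers behind one uniform interface.

These are comparators, not the contribution: k-means, Gaussian-mixture
EM (optionally informed with the generating hyperparameters),
hierarchical linkage, fuzzy c-means, and two random reference
clusterers. Every method returns a 1-based label vector; downstream
scoring is label-permutation invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)

METHODS = ("kmeans", "fuzzy-cmeans", "hier-single", "hier-average",
           "hier-complete", "em-gmm", "em-gmm-informed", "random")


@dataclass(frozen=True)
class BaselineSpec:
    """Which baseline to run and with what options."""

    method: str
    k: int = 2
    seed: int | None = None
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.k < 1:
            raise ValueError("k must be at least 1")


def random_partition(n: int, mode: str, k: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Random reference labelings.

    ``equal-sizes``: uniform over label functions with exactly n/k points
    per label (requires k | n). ``iid-labels``: each point's label
    independent uniform.
    """
    if mode == "equal-sizes":
        if n % k:
            raise ValueError("equal-sizes mode requires k to divide n")
        base = np.repeat(np.arange(1, k + 1), n // k)
        return rng.permutation(base)
    if mode == "iid-labels":
        return rng.integers(1, k + 1, size=n)
    raise ValueError("mode must be 'equal-sizes' or 'iid-labels'")


def _hierarchical(X: np.ndarray, method: str, k: int) -> np.ndarray:
    Z = linkage(pdist(X), method=method)
    return fcluster(Z, t=k, criterion="maxclust")


def run_baseline(X: np.ndarray, spec: BaselineSpec) -> np.ndarray:
    """Run one comparison clusterer; deterministic given ``spec.seed``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k = spec.k
    seed = spec.seed
    opts = dict(spec.options)
    if spec.method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed, **opts)
        return km.fit_predict(X) + 1
    if spec.method == "fuzzy-cmeans":
        from .cluster import FuzzyCMeans
        fcm = FuzzyCMeans(n_clusters=k, random_state=seed, **opts)
        return fcm.fit(X).labels_
    if spec.method.startswith("hier-"):
        return _hierarchical(X, spec.method.removeprefix("hier-"), k)
    if spec.method in ("em-gmm", "em-gmm-informed"):
        kwargs = dict(n_components=k, covariance_type="full",
                      random_state=seed, reg_covar=1e-6)
        if spec.method == "em-gmm-informed":
            # informed: start EM at the hyperparameter-implied covariance
            # (means still come from the k-means init — identical informed
            # means would leave the two components indistinguishable)
            opts.pop("mean", None)
            cov = np.asarray(opts.pop("cov", np.eye(X.shape[1])))
            prec = np.linalg.inv(cov)
            kwargs.update(precisions_init=np.tile(prec, (k, 1, 1)),
                          weights_init=np.full(k, 1.0 / k))
        kwargs.update(opts)
        try:
            gm = GaussianMixture(**kwargs)
            return gm.fit_predict(X) + 1
        except (np.linalg.LinAlgError, ValueError) as exc:
            log.warning("GaussianMixture failed (%s); retrying with strong "
                        "covariance regularization", exc)
            kwargs["reg_covar"] = 1e-2
            gm = GaussianMixture(**kwargs)
            return gm.fit_predict(X) + 1
    if spec.method == "random":
        rng = np.random.default_rng(seed)
        mode = opts.get("mode", "iid-labels")
        return random_partition(X.shape[0], mode, k, rng)
    raise AssertionError("unreachable")
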