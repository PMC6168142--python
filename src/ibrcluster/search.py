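"""Approximate IBR clustering for large point sets.

Exhaustive posterior evaluation is infeasible beyond ~20 points, so the
large-n pipeline (two labels, fixed cluster sizes) proceeds in four
steps: (1) find the maximum-posterior-probability labeling of a small
random subset by exhaustive search; (2) extend it to all points with a
quadratic discriminant whose threshold is chosen so the output cluster
sizes match the size constraint exactly; (3) hill-climb over all
labelings with at most two points clustered differently (size-preserving
pair swaps, best improvement first); (4) keep the highest-probability
labeling over several random restarts. The output is the MAP partition
found; when the "subset" is the whole point set there is nothing to
approximate and the exact risk-minimizing solver is used directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .partitions import (DEFAULT_GUARD, Partition, SizeSpec, canonicalize,
                         enumerate_supported_labelings)
from .robust import ExactIBREngine, _log_weights

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the approximate search."""

    subset_size: int = 10
    restarts: int = 10
    neighborhood: int = 2  # max points re-clustered per move

    def __post_init__(self):
        if self.restarts < 1:
            raise ValueError("need at least one restart")
        if self.neighborhood not in (1, 2):
            raise ValueError("neighborhood must be 1 or 2")


def _subset_sizes(sizes: tuple, m: int) -> tuple:
    """Split the subset size across labels proportionally to the full
    cluster sizes (largest remainder rounding)."""
    n = sum(sizes)
    raw = [s * m / n for s in sizes]
    base = [int(np.floor(r)) for r in raw]
    short = m - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])
    for j in order[:short]:
        base[j] += 1
    if any(b == 0 for b in base):
        raise ValueError("subset too small to populate every cluster")
    return tuple(base)


def map_labeling(X: np.ndarray, model, guard: int = DEFAULT_GUARD) -> np.ndarray:
    """Maximum-posterior-probability labeling by exhaustive enumeration;
    ties broken by the lexicographically smallest label vector."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labelings = enumerate_supported_labelings(X.shape[0], model.label_prior,
                                              guard=guard)
    logw = _log_weights(X, model, labelings)
    best = np.flatnonzero(logw == logw.max())
    return min((labelings[i] for i in best), key=tuple)


def seed_partition(X: np.ndarray, model, config: SearchConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Step 1: MAP labeling of a random subset under the effective model.

    Returns (subset indices, subset labels).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    m = min(config.subset_size, n)
    idx = np.sort(rng.choice(n, size=m, replace=False))
    prior = model.label_prior
    if prior.is_fixed:
        sub_prior = SizeSpec.fixed(_subset_sizes(prior.sizes, m))
    else:
        sub_prior = SizeSpec.unconstrained(prior.n_labels)
    sub_model = model.with_label_prior(sub_prior)
    labels = map_labeling(X[idx], sub_model)
    return idx, labels


def qda_extend(X: np.ndarray, subset_idx: np.ndarray, subset_labels: np.ndarray,
               sizes: tuple, reg: float = 1e-6) -> np.ndarray:
    """Step 2: extend a two-cluster subset labeling to all points.

    Per-cluster sample means/covariances (ridge-regularized; pooled
    fallback when a cluster is too small) give quadratic discriminant
    scores; points are ranked by score difference and the threshold is
    the one making the output sizes match ``sizes`` exactly.
    """
    if len(sizes) != 2:
        raise ValueError("QDA extension supports two clusters")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    sub = X[subset_idx]

    def _moments(pts):
        mu = pts.mean(axis=0)
        if pts.shape[0] >= 2:
            cov = np.cov(pts, rowvar=False).reshape(d, d)
        else:
            cov = np.zeros((d, d))
        return mu, cov

    mus, covs, counts = [], [], []
    for y in (1, 2):
        pts = sub[subset_labels == y]
        counts.append(pts.shape[0])
        mu, cov = _moments(pts)
        mus.append(mu)
        covs.append(cov)
    pooled = None
    for j in range(2):
        cov = covs[j]
        scale = np.mean(np.diag(cov)) if np.any(np.diag(cov) > 0) else 1.0
        cov = cov + reg * scale * np.eye(d)
        if counts[j] < 2 or np.linalg.matrix_rank(covs[j]) < d:
            if pooled is None:
                pall = np.cov(sub, rowvar=False).reshape(d, d)
                pooled = pall + reg * max(np.mean(np.diag(pall)), 1e-12) * np.eye(d)
                log.debug("qda_extend: singular cluster covariance, "
                          "falling back to pooled covariance")
            cov = pooled
        covs[j] = cov

    def _logpdf(mu, cov):
        chol = np.linalg.cholesky(cov)
        sol = np.linalg.solve(chol, (X - mu).T)
        return (-0.5 * np.sum(sol ** 2, axis=0)
                - np.sum(np.log(np.diag(chol))))

    score = _logpdf(mus[0], covs[0]) - _logpdf(mus[1], covs[1])
    order = np.argsort(-score, kind="stable")
    labels = np.full(n, 2, dtype=int)
    labels[order[:sizes[0]]] = 1
    moved = int(np.sum(labels[subset_idx] != subset_labels))
    if moved:
        log.debug("qda_extend: %d subset points crossed the size-constrained "
                  "threshold and were reassigned", moved)
    return labels


def _swap_moves(labels: np.ndarray):
    ones = np.flatnonzero(labels == 1)
    twos = np.flatnonzero(labels == 2)
    for i in ones:
        for j in twos:
            yield i, j


def local_search(labels0: np.ndarray, X: np.ndarray, model,
                 config: SearchConfig | None = None):
    """Step 3: best-improvement hill climbing over size-preserving swaps
    of at most two points. Returns (labels, weight history); the history
    is non-decreasing and the last entry is a local maximum.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels0, dtype=int).copy()
    if not model.label_prior.supports(labels):
        raise ValueError("initial labeling is outside the prior support")
    current = model.log_label_weight(X, labels)
    history = [current]
    while True:
        best_gain, best_move = 0.0, None
        for i, j in _swap_moves(labels):
            labels[i], labels[j] = labels[j], labels[i]
            w = model.log_label_weight(X, labels)
            labels[i], labels[j] = labels[j], labels[i]
            if w - current > best_gain:
                best_gain, best_move = w - current, (i, j)
        if best_move is None:
            break
        i, j = best_move
        labels[i], labels[j] = labels[j], labels[i]
        current += best_gain
        current = model.log_label_weight(X, labels)  # re-anchor, avoids drift
        history.append(current)
    return labels, history


def approx_ibr(X: np.ndarray, model, config: SearchConfig | None = None,
               rng: np.random.Generator | None = None,
               guard: int = DEFAULT_GUARD) -> Partition:
    """Steps 1-4 combined: best-of-restarts MAP partition.

    Deterministic given the rng seed. When ``subset_size >= n`` (and the
    point set is within the exact-enumeration guard) the exact
    risk-minimizing IBR partition is returned instead — the subset is the
    full point set, so no approximation is involved.
    """
    config = config or SearchConfig()
    rng = rng or np.random.default_rng()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if config.subset_size >= n and n <= guard:
        engine = ExactIBREngine(n, model.label_prior, guard=guard)
        part, _, _ = engine.solve(X, model)
        return part
    if model.label_prior.n_labels != 2 or not model.label_prior.is_fixed:
        raise ValueError("approximate search requires a fixed-size "
                         "two-label prior")
    best_w, best_labels = -np.inf, None
    for _ in range(config.restarts):
        idx, sub_labels = seed_partition(X, model, config, rng)
        labels = qda_extend(X, idx, sub_labels, model.label_prior.sizes)
        labels, history = local_search(labels, X, model, config)
        w = history[-1]
        if w > best_w or (w == best_w and
                          tuple(labels) < tuple(best_labels)):
            best_w, best_labels = w, labels.copy()
    return canonicalize(best_labels)
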