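"""Uncertainty classes, effective processes, and robust clusterers.

A state of nature is one separable RLPP; an uncertainty class is a finite
set of states with prior weights. The effective process of the class is
again separable, with the state absorbed into the parameter prior, so its
label-function posterior is the prior-weighted mixture of per-state
posteriors (computed in the log domain). The IBR clusterer is the Bayes
clusterer of the effective process; MCBR and minimax clusterers optimize
over the smaller class of state-optimal partitions and are provided for
reference.

Any object exposing ``log_label_weight(X, labels)`` (sharing the exact
marginal-likelihood convention), ``label_prior`` and ``n_labels`` can act
as a model here; :class:`DiscreteUncertaintyClass` itself satisfies the
protocol, which is precisely how the effective process is realized.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Callable, NamedTuple

import numpy as np
from scipy.special import logsumexp

from .cost import (PartitionDistribution, bayes_partition, cluster_mismatch,
                   cost_matrix, partition_error)
from .partitions import (DEFAULT_GUARD, Partition, SizeSpec, canonicalize,
                         enumerate_partitions, enumerate_supported_labelings)

MAX_STATES = 8


class LabelPosterior(NamedTuple):
    """Posterior over the enumerated support of label functions."""

    labelings: np.ndarray  # (K, n) 1-based labels
    log_weights: np.ndarray  # unnormalized
    probs: np.ndarray  # normalized, sums to 1

    def as_dict(self) -> dict:
        return {tuple(int(v) for v in row): float(p)
                for row, p in zip(self.labelings, self.probs)}


@dataclass(frozen=True)
class DiscreteUncertaintyClass:
    """Finite set of separable RLPP states with prior weights pi(theta)."""

    states: tuple
    weights: np.ndarray

    def __post_init__(self):
        states = tuple(self.states)
        if not states:
            raise ValueError("empty state list")
        w = np.asarray(self.weights, dtype=float)
        if w.size != len(states) or np.any(w < 0):
            raise ValueError("need one nonnegative weight per state")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("state weights must sum to 1")
        prior = states[0].label_prior
        if any(s.label_prior != prior for s in states):
            raise ValueError("all states must share the label prior")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "weights", w)

    @property
    def label_prior(self) -> SizeSpec:
        return self.states[0].label_prior

    @property
    def n_labels(self) -> int:
        return self.label_prior.n_labels

    def with_label_prior(self, spec: SizeSpec) -> "DiscreteUncertaintyClass":
        return replace(
            self, states=tuple(s.with_label_prior(spec) for s in self.states))

    def log_label_weight(self, X: np.ndarray, labels) -> float:
        """Effective-process weight: log sum_theta pi(theta) f(S|phi,theta)
        P(phi). Mixture linearity of the effective separable process."""
        terms = np.array([s.log_label_weight(X, labels) for s in self.states])
        with np.errstate(divide="ignore"):
            logw = np.log(self.weights)
        return float(logsumexp(terms + logw))

    def sample(self, rng: np.random.Generator):
        """Draw a state index from pi, then (points, labels) from it."""
        k = int(rng.choice(len(self.states), p=self.weights))
        X, labels = self.states[k].sample(rng)
        return X, labels, k


def _log_weights(X: np.ndarray, model, labelings: np.ndarray) -> np.ndarray:
    batch = getattr(model, "log_label_weights_batch", None)
    if batch is not None:
        return np.asarray(batch(X, labelings), dtype=float)
    return np.array([model.log_label_weight(X, lab) for lab in labelings])


def label_posterior(X: np.ndarray, model, guard: int = DEFAULT_GUARD) -> LabelPosterior:
    """Normalized posterior over the supported label functions of ``model``.

    Support is enumerated exhaustively (capacity-guarded); normalization
    is done by log-sum-exp, so probabilities sum to one to ~1e-12.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    labelings = enumerate_supported_labelings(n, model.label_prior, guard=guard)
    logw = _log_weights(X, model, labelings)
    probs = np.exp(logw - logsumexp(logw))
    probs = probs / probs.sum()
    return LabelPosterior(labelings=labelings, log_weights=logw, probs=probs)


def partition_posterior(X: np.ndarray, model,
                        guard: int = DEFAULT_GUARD) -> PartitionDistribution:
    """Posterior pmf over partitions: each partition's probability is the
    summed probability of its inducing label functions."""
    post = label_posterior(X, model, guard=guard)
    acc: dict[Partition, float] = {}
    for lab, p in zip(post.labelings, post.probs):
        part = canonicalize(lab)
        acc[part] = acc.get(part, 0.0) + float(p)
    parts = sorted(acc, key=lambda q: q.rgs)
    probs = np.array([acc[q] for q in parts])
    return PartitionDistribution(tuple(parts), probs / probs.sum())


def effective_label_posterior(X: np.ndarray, uncertainty: DiscreteUncertaintyClass,
                              guard: int = DEFAULT_GUARD) -> LabelPosterior:
    """Label posterior under the effective RLPP of the uncertainty class."""
    return label_posterior(X, uncertainty, guard=guard)


class ExactIBREngine:
    """Exhaustive Bayes/IBR solver with all data-independent structure
    (supported labelings, reference partitions, candidate set, cost
    matrix) precomputed once and reused across point sets."""

    def __init__(self, n: int, label_prior: SizeSpec,
                 candidates: list[Partition] | None = None,
                 guard: int = DEFAULT_GUARD):
        self.n = n
        self.label_prior = label_prior
        l = label_prior.n_labels
        self.labelings = enumerate_supported_labelings(n, label_prior, guard=guard)
        refs: dict[Partition, list[int]] = {}
        for i, lab in enumerate(self.labelings):
            refs.setdefault(canonicalize(lab), []).append(i)
        self.refs = sorted(refs, key=lambda q: q.rgs)
        self._ref_rows = [np.array(refs[q]) for q in self.refs]
        if candidates is None:
            candidates = enumerate_partitions(n, l, guard=guard)
        self.candidates = candidates
        self.costs = cost_matrix(self.candidates, self.refs)

    def posterior(self, X: np.ndarray, model) -> tuple[LabelPosterior, PartitionDistribution]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        logw = _log_weights(X, model, self.labelings)
        probs = np.exp(logw - logsumexp(logw))
        probs = probs / probs.sum()
        post = LabelPosterior(self.labelings, logw, probs)
        ref_probs = np.array([probs[rows].sum() for rows in self._ref_rows])
        dist = PartitionDistribution(tuple(self.refs), ref_probs / ref_probs.sum())
        return post, dist

    def solve(self, X: np.ndarray, model) -> tuple[Partition, float, PartitionDistribution]:
        """Bayes partition of X under ``model``: minimal partition error,
        canonical tie-break."""
        _, dist = self.posterior(X, model)
        errs = self.costs @ dist.probs
        best = np.flatnonzero(errs == errs.min())
        winner = min((self.candidates[i] for i in best), key=lambda p: p.rgs)
        return winner, float(errs.min()), dist


def ibr_partition(X: np.ndarray, model,
                  candidates: list[Partition] | None = None,
                  guard: int = DEFAULT_GUARD) -> tuple[Partition, float]:
    """IBR partition: Bayes partition under the effective process.

    ``model`` may be a single separable RLPP (degenerate class) or a
    :class:`DiscreteUncertaintyClass`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    dist = partition_posterior(X, model, guard=guard)
    if candidates is None:
        candidates = enumerate_partitions(X.shape[0], model.n_labels, guard=guard)
    return bayes_partition(candidates, dist)


class IdentityCheck(NamedTuple):
    lhs: float
    rhs: float
    lhs_exact: Fraction
    rhs_exact: Fraction
    se: float


def expected_error_identity_check(clusterer: Callable, uncertainty: DiscreteUncertaintyClass,
                                  n_mc: int, rng: np.random.Generator,
                                  shared: bool = True) -> IdentityCheck:
    """Monte-Carlo check of the effective-process identity
    ``E_theta[eps_theta(zeta)] = eps_eff(zeta)``.

    With ``shared=True`` both sides are estimated from one set of draws:
    the left side groups errors by state and reweights by the empirical
    state frequencies, the right side averages the mixture draws directly.
    Both are returned as exact rationals, where they agree identically.
    With ``shared=False`` the left side uses state-stratified draws with
    the true prior weights and the right side independent mixture draws.
    """
    states = uncertainty.states

    def _err_frac(X, labels) -> Fraction:
        part = clusterer(X)
        n = len(labels)
        mism = round(cluster_mismatch(labels, part,
                                      n_labels=uncertainty.n_labels) * n)
        return Fraction(mism, n)

    if shared:
        ks, errs = [], []
        for _ in range(n_mc):
            X, labels, k = uncertainty.sample(rng)
            ks.append(k)
            errs.append(_err_frac(X, labels))
        rhs = sum(errs, Fraction(0)) / n_mc
        lhs = Fraction(0)
        ks = np.array(ks)
        for k in range(len(states)):
            rows = np.flatnonzero(ks == k)
            if rows.size == 0:
                continue
            mean_k = sum((errs[i] for i in rows), Fraction(0)) / len(rows)
            lhs += Fraction(len(rows), n_mc) * mean_k
        vals = np.array([float(e) for e in errs])
        se = float(vals.std(ddof=1) / np.sqrt(n_mc)) if n_mc > 1 else 0.0
        return IdentityCheck(float(lhs), float(rhs), lhs, rhs, se)

    per_state = max(1, n_mc // len(states))
    lhs = Fraction(0)
    var_lhs = 0.0
    for k, state in enumerate(states):
        errs_k = []
        for _ in range(per_state):
            X, labels = state.sample(rng)
            errs_k.append(_err_frac(X, labels))
        mean_k = sum(errs_k, Fraction(0)) / per_state
        w = Fraction(uncertainty.weights[k]).limit_denominator(10**12)
        lhs += w * mean_k
        vals = np.array([float(e) for e in errs_k])
        var_lhs += float(w) ** 2 * vals.var(ddof=1) / per_state
    errs = []
    for _ in range(n_mc):
        X, labels, _ = uncertainty.sample(rng)
        errs.append(_err_frac(X, labels))
    rhs = sum(errs, Fraction(0)) / n_mc
    vals = np.array([float(e) for e in errs])
    se = float(np.sqrt(var_lhs + vals.var(ddof=1) / n_mc))
    return IdentityCheck(float(lhs), float(rhs), lhs, rhs, se)


def state_partition_errors(X: np.ndarray, uncertainty: DiscreteUncertaintyClass,
                           candidates: list[Partition],
                           guard: int = DEFAULT_GUARD) -> np.ndarray:
    """eps_theta(S, P) for every state (rows) and candidate (columns)."""
    out = np.empty((len(uncertainty.states), len(candidates)))
    for k, state in enumerate(uncertainty.states):
        dist = partition_posterior(X, state, guard=guard)
        out[k] = cost_matrix(candidates, list(dist.partitions)) @ dist.probs
    return out


def _state_bayes_candidates(X, uncertainty, candidates, guard):
    if len(uncertainty.states) > MAX_STATES:
        raise ValueError(
            f"reference-only operators support at most {MAX_STATES} states")
    if candidates is None:
        n = np.atleast_2d(X).shape[0]
        candidates = enumerate_partitions(n, uncertainty.n_labels, guard=guard)
    pool = []
    for state in uncertainty.states:
        dist = partition_posterior(X, state, guard=guard)
        p, _ = bayes_partition(candidates, dist)
        if p not in pool:
            pool.append(p)
    return sorted(pool, key=lambda p: p.rgs)


def mcbr_partition(X: np.ndarray, uncertainty: DiscreteUncertaintyClass,
                   candidates: list[Partition] | None = None,
                   guard: int = DEFAULT_GUARD) -> Partition:
    """Model-constrained Bayesian robust partition: among the states' own
    Bayes partitions, the one minimizing the prior-averaged error."""
    pool = _state_bayes_candidates(X, uncertainty, candidates, guard)
    errs = state_partition_errors(X, uncertainty, pool, guard=guard)
    avg = uncertainty.weights @ errs
    best = np.flatnonzero(avg == avg.min())
    return min((pool[i] for i in best), key=lambda p: p.rgs)


def minimax_partition(X: np.ndarray, uncertainty: DiscreteUncertaintyClass,
                      candidates: list[Partition] | None = None,
                      guard: int = DEFAULT_GUARD) -> Partition:
    """Minimax robust partition: among the states' Bayes partitions, the
    one with the best worst-state error."""
    pool = _state_bayes_candidates(X, uncertainty, candidates, guard)
    errs = state_partition_errors(X, uncertainty, pool, guard=guard)
    worst = errs.max(axis=0)
    best = np.flatnonzero(worst == worst.min())
    return min((pool[i] for i in best), key=lambda p: p.rgs)
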