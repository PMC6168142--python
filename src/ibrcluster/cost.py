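"""Mismatch errors, the natural partition cost, and the Bayes partition.

The clustering error of a proposed partition is measured in units of
misclustered points: the *natural cost* between two partitions is the
minimum fraction of points whose labels disagree over all pairs of label
functions inducing them, which reduces to a maximum-weight matching
between blocks on the contingency table of intersection sizes. The
*partition error* averages this cost over a posterior distribution on
true partitions; its minimizer is the Bayes partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .partitions import Partition, _as_labels


def label_mismatch(phi, psi) -> float:
    """Fraction of points where two label functions disagree."""
    a, b = _as_labels(phi), _as_labels(psi)
    if a.size != b.size:
        raise ValueError("label functions must have equal length")
    return float(np.mean(a != b))


def _contingency(row_labels: np.ndarray, col_labels: np.ndarray,
                 n_rows: int, n_cols: int) -> np.ndarray:
    idx = (row_labels * n_cols + col_labels)
    return np.bincount(idx, minlength=n_rows * n_cols).reshape(n_rows, n_cols)


def _max_overlap(table: np.ndarray) -> int:
    r, c = linear_sum_assignment(table, maximize=True)
    return int(table[r, c].sum())


def cluster_mismatch(phi, p: Partition, n_labels: int | None = None) -> float:
    """Minimum label mismatch between ``phi`` and any labeling inducing ``p``.

    Label-permutation invariant; computed as an optimal assignment of
    blocks of ``p`` to the labels of ``phi`` on their contingency table.
    """
    phi = _as_labels(phi)
    if phi.size != p.n:
        raise ValueError("label function and partition disagree on n")
    l = int(n_labels) if n_labels is not None else int(phi.max())
    k = p.n_blocks
    if k > l:
        raise ValueError(f"partition has {k} blocks but only l={l} labels")
    table = _contingency(phi - 1, np.asarray(p.rgs), l, k)
    return 1.0 - _max_overlap(table) / phi.size


def natural_cost(p: Partition, q: Partition) -> float:
    """Natural partition cost: min fraction of differently-labeled points.

    Equals ``(n - best matched block overlap)/n`` via maximum-weight
    assignment between the blocks of the two partitions; symmetric in its
    arguments.
    """
    if p.n != q.n:
        raise ValueError("partitions must cover the same number of points")
    table = _contingency(np.asarray(p.rgs), np.asarray(q.rgs),
                         p.n_blocks, q.n_blocks)
    return 1.0 - _max_overlap(table) / p.n


def _two_block_mask(p: Partition) -> int:
    return sum(1 << i for i, b in enumerate(p.rgs) if b == 1)


def cost_matrix(candidates: list[Partition], refs: list[Partition]) -> np.ndarray:
    """Natural costs between candidates (rows) and references (columns).

    For two-label problems (all partitions with at most 2 blocks and
    n <= 64) the cost reduces to min(hamming, n - hamming)/n on block
    bitmasks and is fully vectorized; otherwise each entry is an
    assignment problem.
    """
    if not candidates or not refs:
        raise ValueError("candidate and reference lists must be nonempty")
    n = candidates[0].n
    two_block = (n <= 64
                 and all(p.n_blocks <= 2 for p in candidates)
                 and all(q.n_blocks <= 2 for q in refs))
    if two_block:
        cm = np.array([_two_block_mask(p) for p in candidates], dtype=np.uint64)
        rm = np.array([_two_block_mask(q) for q in refs], dtype=np.uint64)
        ham = np.bitwise_count(cm[:, None] ^ rm[None, :]).astype(float)
        return np.minimum(ham, n - ham) / n
    out = np.empty((len(candidates), len(refs)))
    for i, p in enumerate(candidates):
        for j, q in enumerate(refs):
            out[i, j] = natural_cost(p, q)
    return out


@dataclass(frozen=True)
class PartitionDistribution:
    """Probability mass function over reference partitions."""

    partitions: tuple
    probs: np.ndarray

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if len(self.partitions) != probs.size:
            raise ValueError("one probability per partition required")
        if np.any(probs < -1e-15):
            raise ValueError("negative partition probability")
        if abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("partition probabilities must sum to 1")
        if len(set(self.partitions)) != len(self.partitions):
            raise ValueError("reference partitions must be distinct")
        object.__setattr__(self, "partitions", tuple(self.partitions))
        object.__setattr__(self, "probs", probs)

    @classmethod
    def degenerate(cls, p: Partition) -> "PartitionDistribution":
        return cls((p,), np.array([1.0]))

    @property
    def n(self) -> int:
        return self.partitions[0].n


def partition_error(p: Partition, dist: PartitionDistribution) -> float:
    """Expected natural cost of ``p`` against the reference distribution."""
    if p.n != dist.n:
        raise ValueError("partition and distribution disagree on n")
    costs = cost_matrix([p], list(dist.partitions))[0]
    return float(costs @ dist.probs)


def partition_errors(candidates: list[Partition],
                     dist: PartitionDistribution) -> np.ndarray:
    """Partition error of every candidate (the cost matrix times the pmf)."""
    return cost_matrix(candidates, list(dist.partitions)) @ dist.probs


def bayes_partition(candidates: list[Partition],
                    dist: PartitionDistribution) -> tuple[Partition, float]:
    """Candidate with minimal partition error; ties go to the canonically
    smallest encoding."""
    if not candidates:
        raise ValueError("empty candidate list")
    errs = partition_errors(candidates, dist)
    best = np.flatnonzero(errs == errs.min())
    winner = min((candidates[i] for i in best), key=lambda p: p.rgs)
    return winner, float(errs.min())
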