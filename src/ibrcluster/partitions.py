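"""Combinatorics of label functions and set partitions.

A clustering of ``n`` points is described either by a *label function* — a
vector assigning each point a label in ``{1..l}`` — or by a *partition*,
the set of blocks those labels induce. Every partition is induced by
``l!/(l-k)!`` distinct label functions (``k`` = number of blocks), so all
downstream error computations work on canonical partitions. The canonical
encoding is the restricted-growth string (RGS): point ``i`` is tagged with
the index of its block, blocks numbered in order of first appearance. The
RGS is unique per partition (label-permutation invariant) and its
lexicographic order is the total deterministic order used everywhere for
tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations, product

import numpy as np

#: Exhaustive enumeration is refused above this many points (two-label
#: problems reach ~2^21 partitions here, the practical ceiling for the
#: exact clusterer).
DEFAULT_GUARD = 22

# Generic (l > 2) enumeration grows like Bell numbers; keep it small.
_GENERIC_GUARD = 16


class CapacityError(RuntimeError):
    """An exhaustive enumeration would be infeasibly large."""


def _as_labels(labels) -> np.ndarray:
    arr = np.asarray(labels, dtype=int)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("label function must be a nonempty 1-d integer vector")
    if np.any(arr < 1):
        raise ValueError("labels must be positive (1-based) integers")
    return arr


class Partition:
    """A set partition of ``{1..n}`` in canonical restricted-growth form."""

    __slots__ = ("_rgs",)

    def __init__(self, rgs):
        rgs = tuple(int(b) for b in rgs)
        if not rgs:
            raise ValueError("empty partition")
        top = -1
        for b in rgs:
            if b < 0 or b > top + 1:
                raise ValueError(f"not a restricted-growth string: {rgs}")
            top = max(top, b)
        self._rgs = rgs

    # -- constructors -------------------------------------------------
    @classmethod
    def from_labels(cls, labels) -> "Partition":
        arr = _as_labels(labels)
        seen: dict[int, int] = {}
        rgs = []
        for lab in arr.tolist():
            if lab not in seen:
                seen[lab] = len(seen)
            rgs.append(seen[lab])
        return cls(rgs)

    @classmethod
    def from_blocks(cls, blocks) -> "Partition":
        blocks = [sorted(int(i) for i in b) for b in blocks]
        n = sum(len(b) for b in blocks)
        labels = np.zeros(n, dtype=int)
        flat = sorted(i for b in blocks for i in b)
        if flat != list(range(1, n + 1)):
            raise ValueError("blocks must be disjoint and cover {1..n}")
        for j, b in enumerate(blocks, start=1):
            for i in b:
                labels[i - 1] = j
        return cls.from_labels(labels)

    # -- views --------------------------------------------------------
    @property
    def rgs(self) -> tuple:
        return self._rgs

    @property
    def n(self) -> int:
        return len(self._rgs)

    @property
    def n_blocks(self) -> int:
        return max(self._rgs) + 1

    @property
    def blocks(self) -> tuple:
        out: list[list[int]] = [[] for _ in range(self.n_blocks)]
        for i, b in enumerate(self._rgs, start=1):
            out[b].append(i)
        return tuple(tuple(b) for b in out)

    def block_sizes(self) -> tuple:
        counts = np.bincount(np.asarray(self._rgs))
        return tuple(int(c) for c in counts)

    def label_vector(self) -> np.ndarray:
        """Canonical 1-based label representation of the partition."""
        return np.asarray(self._rgs, dtype=int) + 1

    # -- protocol -----------------------------------------------------
    def __eq__(self, other):
        return isinstance(other, Partition) and self._rgs == other._rgs

    def __hash__(self):
        return hash(self._rgs)

    def __lt__(self, other):
        return self._rgs < other._rgs

    def __le__(self, other):
        return self._rgs <= other._rgs

    def __repr__(self):
        return f"Partition(blocks={self.blocks})"


def canonicalize(labels) -> Partition:
    """Map a label function to the canonical partition it induces.

    Two label functions differing only by a permutation of the labels map
    to the same :class:`Partition`.
    """
    return Partition.from_labels(labels)


@dataclass(frozen=True)
class SizeSpec:
    """Prior support over label functions.

    ``sizes`` gives the exact number of points per label (the fixed-size,
    equally-likely prior used throughout); ``sizes=None`` means every
    label function with up to ``n_labels`` labels is equally likely.
    """

    n_labels: int
    sizes: tuple | None = None

    def __post_init__(self):
        if self.n_labels < 1:
            raise ValueError("need at least one label")
        if self.sizes is not None:
            sizes = tuple(int(s) for s in self.sizes)
            if len(sizes) != self.n_labels:
                raise ValueError("one size per label required")
            if any(s <= 0 for s in sizes):
                raise ValueError("cluster sizes must be positive")
            object.__setattr__(self, "sizes", sizes)

    @classmethod
    def fixed(cls, sizes) -> "SizeSpec":
        sizes = tuple(int(s) for s in sizes)
        return cls(n_labels=len(sizes), sizes=sizes)

    @classmethod
    def unconstrained(cls, n_labels: int) -> "SizeSpec":
        return cls(n_labels=int(n_labels), sizes=None)

    @property
    def is_fixed(self) -> bool:
        return self.sizes is not None

    @property
    def n(self) -> int | None:
        return None if self.sizes is None else sum(self.sizes)

    def supports(self, labels) -> bool:
        arr = _as_labels(labels)
        if np.any(arr > self.n_labels):
            return False
        if self.sizes is None:
            return True
        if arr.size != self.n:
            return False
        counts = np.bincount(arr, minlength=self.n_labels + 1)[1:]
        return tuple(int(c) for c in counts) == self.sizes

    def log_prior(self, labels) -> float:
        """Log label prior up to its (support-wide constant) normalizer."""
        return 0.0 if self.supports(labels) else -np.inf

    def partition_in_support(self, p: Partition) -> bool:
        if self.sizes is None:
            return p.n_blocks <= self.n_labels
        return sorted(p.block_sizes()) == sorted(self.sizes)


def _two_block_masks(n: int):
    """RGS tails (as ints) for all partitions of n points into <= 2 blocks."""
    for m in range(1 << (n - 1)):
        yield (0,) + tuple((m >> (n - 2 - j)) & 1 for j in range(n - 1))


def _generic_rgs(n: int, max_blocks: int):
    rgs = [0] * n

    def rec(i: int, top: int):
        if i == n:
            yield tuple(rgs)
            return
        for b in range(min(top + 1, max_blocks - 1) + 1):
            rgs[i] = b
            yield from rec(i + 1, max(top, b))

    yield from rec(1, 0)


def enumerate_partitions(n: int, l: int, spec: SizeSpec | None = None,
                         guard: int = DEFAULT_GUARD) -> list[Partition]:
    """Enumerate partitions of ``{1..n}`` with at most ``l`` blocks.

    With a fixed-size ``spec``, only partitions whose block-size multiset
    matches the specified cluster sizes are returned (e.g. n=10 with sizes
    (5,5) yields the C(10,5)/2 = 126 equal-split partitions). Without a
    spec all partitions with up to ``l`` blocks are returned, including
    the degenerate single-block partition, so for l=2 the count is
    2^(n-1). Output order is lexicographic in the canonical RGS encoding
    and is the deterministic tie-break order used downstream.
    """
    if n < 1 or l < 1:
        raise ValueError("need n >= 1 and l >= 1")
    if n > guard:
        raise CapacityError(
            f"exhaustive enumeration refused for n={n} > guard={guard}")
    if spec is not None and spec.is_fixed:
        if sum(spec.sizes) != n:
            raise ValueError("fixed sizes must sum to n")
        if len(spec.sizes) > l:
            raise ValueError("more size entries than labels")
        if len(spec.sizes) == 2 and l == 2:
            a, b = spec.sizes
            out = []
            # block containing point 1 may take either specified size
            for s in sorted({a, b}):
                for rest in combinations(range(2, n + 1), s - 1):
                    block0 = set((1,) + rest)
                    rgs = [0 if i in block0 else 1 for i in range(1, n + 1)]
                    out.append(Partition(rgs))
            out.sort(key=lambda p: p.rgs)
            return out
        if n > _GENERIC_GUARD:
            raise CapacityError(
                f"generic fixed-size enumeration refused for n={n}")
        want = sorted(spec.sizes)
        return [Partition(r) for r in _generic_rgs(n, l)
                if sorted(np.bincount(r).tolist()) == want]
    if l == 2:
        return [Partition(r) for r in _two_block_masks(n)]
    if n > _GENERIC_GUARD:
        raise CapacityError(f"generic enumeration refused for n={n}")
    return [Partition(r) for r in _generic_rgs(n, l)]


def inducing_label_functions(p: Partition, l: int) -> list[np.ndarray]:
    """All label functions with ``l`` labels inducing partition ``p``.

    There are exactly ``l!/(l-k)!`` of them, ``k`` being the number of
    blocks; each canonicalizes back to ``p``.
    """
    k = p.n_blocks
    if k > l:
        raise ValueError(f"partition has {k} blocks but only l={l} labels")
    rgs = np.asarray(p.rgs)
    return [np.asarray(perm)[rgs] for perm in permutations(range(1, l + 1), k)]


def enumerate_supported_labelings(n: int, spec: SizeSpec,
                                  guard: int = DEFAULT_GUARD) -> np.ndarray:
    """All label functions in the support of ``spec``, as a (K, n) array.

    Order is lexicographic in the label vector, hence deterministic.
    """
    if n > guard:
        raise CapacityError(f"labeling enumeration refused for n={n}")
    l = spec.n_labels
    if spec.is_fixed:
        if spec.n != n:
            raise ValueError("fixed sizes must sum to n")
        if l == 2:
            n1 = spec.sizes[0]
            rows = []
            for ones in combinations(range(n), n1):
                lab = np.full(n, 2, dtype=int)
                lab[list(ones)] = 1
                rows.append(lab)
            rows.sort(key=tuple)
            return np.asarray(rows)
        rows = []

        def rec(i, remaining, cur):
            if i == n:
                rows.append(tuple(cur))
                return
            for y in range(l):
                if remaining[y] > 0:
                    remaining[y] -= 1
                    cur.append(y + 1)
                    rec(i + 1, remaining, cur)
                    cur.pop()
                    remaining[y] += 1

        rec(0, list(spec.sizes), [])
        return np.asarray(rows)
    if l ** n > 1 << guard:
        raise CapacityError("unconstrained labeling enumeration too large")
    return np.asarray(list(product(range(1, l + 1), repeat=n)))


def read_labels(path) -> np.ndarray:
    """Read a whitespace-delimited 1-based label vector from text."""
    return _as_labels(np.loadtxt(path, dtype=int, ndmin=1))


def write_labels(path, labels) -> None:
    np.savetxt(path, np.asarray(labels, dtype=int)[None, :], fmt="%d")
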