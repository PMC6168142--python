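"""Granulometric features of binary grain images, and their IBR posterior.

The grain model: a binary image is a disjoint union of N scaled
primitives (unit-area equilateral triangles and 1:5 vertical rods) with
gamma-distributed radii. Features are the first two moments of the
pattern spectra under vertical and horizontal line openings; given the
radii these moments are exact linear images z = M x of the radius power
sums x (components [x_11, x_21, x_12, x_22], primitives i in rows,
moment order k: x_ik = sum_j r_ij^(k+2) / sum_ij r_ij^2), so features
are simulated analytically from radii. Rasterized-image rendering and
opening-based pattern spectra exist only as a validation path for the
moment constants.

For many grains the feature vector is asymptotically Gaussian with an
analytic mean; the covariance (whose closed form lives behind the
asymptotic theory) is estimated once per parameter point by Monte Carlo
and cached. Two exact structural reductions keep that affordable: the
scale parameter enters covariances as D cov D with
D = diag(beta, beta, beta^2, beta^2) (pathwise gamma scale property),
and the second class equals the first with the primitive roles swapped,
i.e. a fixed coordinate permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .partitions import DEFAULT_GUARD, SizeSpec, _as_labels

# Pattern-spectrum moment constants mu^(k)(primitive, line element):
# triangle/rod against vertical (B1) and horizontal (B2) lines.
MU1_TRI_V = 2.0 * 3.0 ** -0.75
MU1_TRI_H = 4.0 * 3.0 ** -1.25
MU1_ROD_V = 5.0 ** 0.5
MU1_ROD_H = 5.0 ** -0.5
MU2_TRI_V = 0.5 * 3.0 ** 0.5
MU2_TRI_H = 2.0 * 3.0 ** -0.5
MU2_ROD_V = 5.0
MU2_ROD_H = 5.0 ** -1

#: Coordinate permutation realizing the swap of the two primitives
#: (x_11 <-> x_21, x_12 <-> x_22).
PRIMITIVE_SWAP = np.array([[0, 1, 0, 0],
                           [1, 0, 0, 0],
                           [0, 0, 0, 1],
                           [0, 0, 1, 0]], dtype=float)


def moment_matrix() -> np.ndarray:
    """The 4x4 matrix M with z = M x.

    Moment orders do not mix, giving the block-zero layout: rows are
    (first moment, vertical), (first, horizontal), (second, vertical),
    (second, horizontal); columns follow x = [x_11, x_21, x_12, x_22].
    """
    return np.array([
        [MU1_TRI_V, MU1_ROD_V, 0.0, 0.0],
        [MU1_TRI_H, MU1_ROD_H, 0.0, 0.0],
        [0.0, 0.0, MU2_TRI_V, MU2_ROD_V],
        [0.0, 0.0, MU2_TRI_H, MU2_ROD_H],
    ])


def gamma_moments(alpha: float, k: int) -> float:
    """Normalized gamma moment gamma_ik = Gamma(alpha+k)/Gamma(alpha),
    i.e. the rising factorial alpha (alpha+1) ... (alpha+k-1)."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if int(k) != k or k < 1:
        raise ValueError("moment order must be a positive integer")
    return float(np.prod(alpha + np.arange(int(k))))


@dataclass(frozen=True)
class GrainModel:
    """Two-primitive grain population: proportions b, gamma(alpha_i, beta)
    radii (shared scale), n_grains grains per image."""

    alphas: tuple = (1.95, 1.97)
    beta: float = 2.0
    proportions: tuple = (0.5, 0.5)
    n_grains: int = 1000

    def __post_init__(self):
        a = tuple(float(v) for v in self.alphas)
        b = tuple(float(v) for v in self.proportions)
        if len(a) != 2 or len(b) != 2:
            raise ValueError("two primitives expected")
        if any(v <= 0 for v in a) or self.beta <= 0:
            raise ValueError("gamma parameters must be positive")
        if any(v < 0 or v > 1 for v in b) or abs(sum(b) - 1.0) > 1e-9:
            raise ValueError("proportions must be in [0,1] and sum to 1")
        if self.n_grains < 1:
            raise ValueError("need at least one grain")
        object.__setattr__(self, "alphas", a)
        object.__setattr__(self, "proportions", b)
        object.__setattr__(self, "beta", float(self.beta))


def sample_features(model: GrainModel, rng: np.random.Generator,
                    size: int | None = None, fixed_counts: bool = False,
                    chunk: int = 2000) -> np.ndarray:
    """Draw feature vectors x = [x_11, x_21, x_12, x_22] from the model.

    Each draw assigns the n_grains grains to primitives (binomially by
    default, deterministically rounded counts with ``fixed_counts``),
    draws gamma radii, and forms the exact power-sum ratios. Returns a
    4-vector for ``size=None`` and a (size, 4) array otherwise.
    """
    reps = 1 if size is None else int(size)
    n = model.n_grains
    a1, a2 = model.alphas
    b1 = model.proportions[0]
    out = np.empty((reps, 4))
    for lo in range(0, reps, chunk):
        hi = min(lo + chunk, reps)
        m = hi - lo
        if fixed_counts:
            n1 = int(round(n * b1))
            is_tri = np.zeros((m, n), dtype=bool)
            is_tri[:, :n1] = True
        else:
            is_tri = rng.random((m, n)) < b1
        shapes = np.where(is_tri, a1, a2)
        r = rng.gamma(shapes) * model.beta
        r2 = r * r
        denom = r2.sum(axis=1)
        if np.any(denom == 0):
            raise ValueError("degenerate radii draw")
        r3 = r2 * r
        r4 = r2 * r2
        tri = is_tri.astype(float)
        rod = 1.0 - tri
        n_tri = is_tri.sum(axis=1)
        if np.any(n_tri == 0) or np.any(n_tri == n):
            warnings.warn("a draw contained a single primitive type; the "
                          "other primitive's feature components are zero")
        out[lo:hi, 0] = (r3 * tri).sum(axis=1) / denom
        out[lo:hi, 1] = (r3 * rod).sum(axis=1) / denom
        out[lo:hi, 2] = (r4 * tri).sum(axis=1) / denom
        out[lo:hi, 3] = (r4 * rod).sum(axis=1) / denom
    return out[0] if size is None else out


def asymptotic_mean(proportions, beta: float, alphas) -> np.ndarray:
    """Large-N mean of the feature vector.

    (1/(b1 g12 + b2 g22)) [b1 g13 beta, b2 g23 beta,
                           b1 g14 beta^2, b2 g24 beta^2].
    """
    b1, b2 = proportions
    a1, a2 = alphas
    g = {(i, k): gamma_moments(a, k)
         for i, a in ((1, a1), (2, a2)) for k in (2, 3, 4)}
    denom = b1 * g[(1, 2)] + b2 * g[(2, 2)]
    return np.array([b1 * g[(1, 3)] * beta,
                     b2 * g[(2, 3)] * beta,
                     b1 * g[(1, 4)] * beta ** 2,
                     b2 * g[(2, 4)] * beta ** 2]) / denom


_COV_CACHE: dict = {}


def estimate_feature_covariance(model: GrainModel, reps: int = 10_000,
                                seed: int = 0) -> np.ndarray:
    """Monte-Carlo estimate of the feature covariance, cached by
    (model, reps, seed)."""
    if reps < 100:
        warnings.warn("fewer than 100 covariance replicates; the estimate "
                      "will be very noisy")
    key = (model.alphas, model.beta, model.proportions, model.n_grains,
           int(reps), int(seed))
    hit = _COV_CACHE.get(key)
    if hit is not None:
        return hit
    rng = np.random.default_rng(seed)
    draws = sample_features(model, rng, size=reps)
    cov = np.cov(draws, rowvar=False)
    cov = 0.5 * (cov + cov.T)
    _COV_CACHE[key] = cov
    return cov


def beta_scaling(beta: float) -> np.ndarray:
    """diag(beta, beta, beta^2, beta^2): how the scale parameter enters
    the first- and second-order feature components."""
    return np.diag([beta, beta, beta ** 2, beta ** 2])


@dataclass(frozen=True)
class GranularPriorGrid:
    """Discrete priors of the granular uncertainty class.

    ``rho`` (class-1 triangle proportion) is uniform on ``rho_values``;
    the state ``theta`` is uniform on ``theta_values`` and fixes the
    class scales beta_1 = theta, beta_2 = beta_total - theta. The alpha
    table: class 1 has triangle alpha 1.95 / rod 1.97, class 2 the
    reverse; class-2 proportions are (1-rho, rho).
    """

    rho_values: tuple = tuple(np.linspace(0.45, 0.55, 500))
    theta_values: tuple = tuple(np.linspace(1.75, 2.0, 10))
    alphas_class1: tuple = (1.95, 1.97)
    beta_total: float = 3.75
    n_grains: int = 1000

    def __post_init__(self):
        object.__setattr__(self, "rho_values",
                           tuple(float(v) for v in self.rho_values))
        object.__setattr__(self, "theta_values",
                           tuple(float(v) for v in self.theta_values))

    def class_params(self, rho: float, theta: float, y: int):
        """(proportions, alphas, beta) of class ``y`` at grid point
        (rho, theta)."""
        a1, a2 = self.alphas_class1
        if y == 1:
            return (rho, 1.0 - rho), (a1, a2), theta
        if y == 2:
            return (1.0 - rho, rho), (a2, a1), self.beta_total - theta
        raise ValueError("two classes only")

    def grain_model(self, rho: float, theta: float, y: int) -> GrainModel:
        b, a, beta = self.class_params(rho, theta, y)
        return GrainModel(alphas=a, beta=beta, proportions=b,
                          n_grains=self.n_grains)


class GranularEffectiveModel:
    """Effective separable process of the granular uncertainty class.

    Labels have a fixed-size uniform prior; conditionally on the grid
    point (theta, rho) each class's feature vector is Gaussian with the
    analytic asymptotic mean and the cached Monte-Carlo covariance
    (estimated once per rho at unit scale for class 1; class 2 and other
    scales follow by the exact permutation/scaling reductions).
    """

    def __init__(self, grid: GranularPriorGrid, label_prior: SizeSpec,
                 cov_reps: int = 10_000, cov_seed: int = 0):
        if label_prior.n_labels != 2 or not label_prior.is_fixed:
            raise ValueError("the granular model uses a fixed-size "
                             "two-class label prior")
        self.grid = grid
        self.label_prior = label_prior
        self.cov_reps = int(cov_reps)
        self.cov_seed = int(cov_seed)
        self._build()

    n_labels = 2

    def _build(self):
        grid = self.grid
        rhos = np.asarray(grid.rho_values)
        thetas = np.asarray(grid.theta_values)
        R, T = rhos.size, thetas.size
        seeds = np.random.SeedSequence(self.cov_seed).generate_state(R)
        base = np.empty((R, 4, 4))
        for i, rho in enumerate(rhos):
            m = GrainModel(alphas=grid.alphas_class1, beta=1.0,
                           proportions=(rho, 1.0 - rho),
                           n_grains=grid.n_grains)
            base[i] = estimate_feature_covariance(
                m, reps=self.cov_reps, seed=int(seeds[i] & 0x7FFFFFFF))
        P = PRIMITIVE_SWAP
        means = np.empty((T, R, 2, 4))
        covs = np.empty((T, R, 2, 4, 4))
        for t, theta in enumerate(thetas):
            for y in (1, 2):
                b, a, beta = grid.class_params(0.5, theta, y)  # beta only
                D = beta_scaling(beta)
                for i, rho in enumerate(rhos):
                    b, a, _ = grid.class_params(rho, theta, y)
                    means[t, i, y - 1] = asymptotic_mean(b, beta, a)
                    S = base[i] if y == 1 else P @ base[i] @ P
                    covs[t, i, y - 1] = D @ S @ D
        flat_cov = covs.reshape(-1, 4, 4)
        try:
            np.linalg.cholesky(flat_cov)
        except np.linalg.LinAlgError as exc:
            from .gaussian import ConditioningError
            raise ConditioningError(
                "a grid covariance is not positive-definite") from exc
        sign, logdet = np.linalg.slogdet(flat_cov)
        self._means = means.reshape(T * R, 2, 4)  # grid flattened, G = T*R
        self._inv = np.linalg.inv(flat_cov).reshape(T * R, 2, 4, 4)
        self._logdet = logdet.reshape(T * R, 2)
        self._log_prior = -np.log(T * R)  # uniform, independent grids
        self._shape = (T, R)

    def with_label_prior(self, spec: SizeSpec) -> "GranularEffectiveModel":
        clone = object.__new__(GranularEffectiveModel)
        clone.__dict__.update(self.__dict__)
        clone.label_prior = spec
        return clone

    def _point_loglik(self, X: np.ndarray) -> np.ndarray:
        """(G, 2, n) log densities of every point under every grid point
        and class."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        diff = X[None, None, :, :] - self._means[:, :, None, :]
        quad = np.einsum("gyni,gyij,gynj->gyn", diff, self._inv, diff)
        return -0.5 * (4 * np.log(2 * np.pi)
                       + self._logdet[:, :, None] + quad)

    def log_label_weights_batch(self, X: np.ndarray,
                                labelings: np.ndarray) -> np.ndarray:
        labelings = np.atleast_2d(np.asarray(labelings, dtype=int))
        L = self._point_loglik(X)
        supported = np.array([self.label_prior.supports(lab)
                              for lab in labelings])
        m1 = (labelings == 1).astype(float)
        m2 = (labelings == 2).astype(float)
        per_grid = L[:, 0, :] @ m1.T + L[:, 1, :] @ m2.T  # (G, K)
        out = logsumexp(per_grid + self._log_prior, axis=0)
        out[~supported] = -np.inf
        return out

    def log_label_weight(self, X: np.ndarray, labels) -> float:
        labels = _as_labels(labels)
        return float(self.log_label_weights_batch(X, labels[None, :])[0])


def granular_label_posterior(X: np.ndarray, grid: GranularPriorGrid,
                             label_prior: SizeSpec,
                             cov_reps: int = 10_000, cov_seed: int = 0,
                             model: GranularEffectiveModel | None = None,
                             guard: int = DEFAULT_GUARD):
    """Posterior over label functions of a set of feature vectors under
    the granular effective process."""
    from .robust import label_posterior as _generic
    if model is None:
        model = GranularEffectiveModel(grid, label_prior,
                                       cov_reps=cov_reps, cov_seed=cov_seed)
    return _generic(X, model, guard=guard)


# ---------------------------------------------------------------------------
# Optional image-based validation path
# ---------------------------------------------------------------------------

def rasterize_triangle(r: float, pad: int = 4) -> np.ndarray:
    """Binary raster of a unit-area equilateral triangle (horizontal base)
    scaled by r."""
    from skimage.draw import polygon
    side = 2.0 * 3.0 ** -0.25 * r
    height = 3.0 ** 0.25 * r
    H = int(np.ceil(height)) + 2 * pad
    W = int(np.ceil(side)) + 2 * pad
    rows = np.array([H - pad, H - pad, pad])
    cols = np.array([pad, pad + side, pad + side / 2.0])
    img = np.zeros((H, W), dtype=bool)
    rr, cc = polygon(rows, cols, shape=img.shape)
    img[rr, cc] = True
    return img


def rasterize_rod(r: float, pad: int = 4) -> np.ndarray:
    """Binary raster of a unit-area 1:5 vertical rod scaled by r."""
    width = 5.0 ** -0.5 * r
    height = 5.0 ** 0.5 * r
    H = int(np.ceil(height)) + 2 * pad
    W = int(np.ceil(width)) + 2 * pad
    img = np.zeros((H, W), dtype=bool)
    img[pad:pad + int(round(height)), pad:pad + max(1, int(round(width)))] = True
    return img


def pattern_spectrum_moment(image: np.ndarray, element: str = "vertical",
                            k: int = 1) -> float:
    """k-th moment of the pattern spectrum of a binary image under
    line-segment openings.

    Successive openings by length-t lines give the (non-increasing) size
    distribution Omega(t); the normalized increments form a probability
    distribution over sizes whose k-th moment is returned.
    """
    from skimage.morphology import opening as binary_opening
    img = np.asarray(image, dtype=bool)
    if img.ndim != 2 or not img.any():
        raise ValueError("need a nonempty 2-d binary image")
    if element not in ("vertical", "horizontal"):
        raise ValueError("element must be 'vertical' or 'horizontal'")
    area0 = float(img.sum())
    moment = 0.0
    prev_area = area0
    t = 1
    limit = img.shape[0] if element == "vertical" else img.shape[1]
    while prev_area > 0 and t <= limit + 1:
        t += 1
        fp = np.ones((t, 1), dtype=bool) if element == "vertical" \
            else np.ones((1, t), dtype=bool)
        area = float(binary_opening(img, fp).sum())
        if area > prev_area + 1e-9:
            raise AssertionError("opening must be anti-extensive")
        mass = (prev_area - area) / area0
        moment += mass * float(t - 1) ** k
        prev_area = area
    return moment


def size_distribution(image: np.ndarray, element: str = "vertical") -> np.ndarray:
    """Areas Omega(t) of successive line openings, t = 1, 2, ... (until
    empty); non-increasing by anti-extensivity."""
    from skimage.morphology import opening as binary_opening
    img = np.asarray(image, dtype=bool)
    areas = [float(img.sum())]
    t = 1
    limit = img.shape[0] if element == "vertical" else img.shape[1]
    while areas[-1] > 0 and t <= limit + 1:
        t += 1
        fp = np.ones((t, 1), dtype=bool) if element == "vertical" \
            else np.ones((1, t), dtype=bool)
        areas.append(float(binary_opening(img, fp).sum()))
    return np.asarray(areas)
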