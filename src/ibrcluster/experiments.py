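"""Config-driven reproduction of the two benchmark studies.

The Gaussian study draws states of nature (cluster covariances from an
inverse-Wishart), one point set per state, runs every requested
clusterer on the same draws, and scores each output partition by its
cluster mismatch against the generating labels. The granular study does
the same over the theta grid of the grain-sizing uncertainty class with
4-d granulometric feature vectors. One master seed spawns per-replicate
streams so all methods see identical data.
"""

from __future__ import annotations

import platform
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import BaselineSpec, run_baseline
from .cost import cluster_mismatch
from .cost import PartitionDistribution  # noqa: F401  (re-export for configs)
from .gaussian import GaussianRLPPSpec
from .granulometry import GranularEffectiveModel, GranularPriorGrid
from .partitions import SizeSpec, canonicalize
from .robust import ExactIBREngine
from .search import SearchConfig, approx_ibr

GAUSSIAN_METHODS = ("ibr", "kmeans", "fuzzy-cmeans", "hier-single",
                    "hier-average", "hier-complete", "em-gmm",
                    "em-gmm-informed", "random")
GRANULAR_METHODS = ("ibr", "kmeans", "fuzzy-cmeans", "hier-single",
                    "hier-average", "hier-complete", "em-gmm", "random")


@dataclass(frozen=True)
class GaussianStudyConfig:
    """Gaussian uncertainty-class benchmark (native design: d in
    {1, 2, 10, 100, 1000}, n in {10, 100}, 1000 replicates; defaults here
    are a desk-scale subset)."""

    dims: tuple = (1, 2, 10)
    n: int = 10
    replicates: int = 200
    methods: tuple = GAUSSIAN_METHODS
    seed: int = 0
    sizes: tuple | None = None  # None -> equal split
    max_exact_n: int = 20
    subset_size: int = 10
    restarts: int = 10
    random_mode: str = "iid-labels"


@dataclass(frozen=True)
class GranularStudyConfig:
    """Granular-imaging benchmark (native design: 500 image sets per
    theta, rho grid of 500; defaults are the desk-scale design)."""

    sizes: tuple = (5, 5)
    replicates_per_theta: int = 50
    rho_grid: int = 100
    theta_grid: int = 10
    n_grains: int = 1000
    cov_reps: int = 10_000
    methods: tuple = GRANULAR_METHODS
    seed: int = 0
    random_mode: str = "iid-labels"
    fixed_counts: bool = False


@dataclass
class StudyResult:
    """Aggregated benchmark output plus the per-replicate error table."""

    table: pd.DataFrame
    errors: pd.DataFrame
    config: object = None
    seeds: dict = field(default_factory=dict)


def _score(true_labels, labels_or_partition, n_labels=2) -> float:
    part = labels_or_partition
    if not hasattr(part, "rgs"):
        part = canonicalize(part)
    return cluster_mismatch(true_labels, part, n_labels=n_labels)


def _baseline_labels(method, X, seed, config, informed=None):
    opts = {}
    if method == "random":
        opts["mode"] = config.random_mode
    if method == "em-gmm-informed" and informed is not None:
        opts.update(informed)
    return run_baseline(X, BaselineSpec(method=method, k=2, seed=seed,
                                        options=opts))


def run_gaussian_study(config: GaussianStudyConfig) -> StudyResult:
    """Run the Gaussian benchmark and aggregate mean errors per (method, d)."""
    n = config.n
    sizes = config.sizes or (n // 2, n - n // 2)
    prior = SizeSpec.fixed(sizes)
    rows = []
    master = np.random.SeedSequence(config.seed)
    dim_seeds = master.spawn(len(config.dims))
    exact = n <= config.max_exact_n
    engine = ExactIBREngine(n, prior) if exact and "ibr" in config.methods \
        else None
    t0 = time.perf_counter()
    for d, dim_seed in zip(config.dims, dim_seeds):
        spec = GaussianRLPPSpec.symmetric(d, prior)
        informed = {"mean": np.zeros(d), "cov": np.eye(d)}  # psi/(kappa-d-1)=I
        rep_seeds = dim_seed.spawn(config.replicates)
        for r, rep_seed in enumerate(rep_seeds):
            data_rng = np.random.default_rng(rep_seed)
            X, true_labels, _ = spec.sample(data_rng)
            method_seed = int(rep_seed.generate_state(1)[0] & 0x7FFFFFFF)
            for method in config.methods:
                tic = time.perf_counter()
                if method == "ibr":
                    if exact:
                        part, _, _ = engine.solve(X, spec)
                    else:
                        sc = SearchConfig(subset_size=config.subset_size,
                                          restarts=config.restarts)
                        part = approx_ibr(
                            X, spec, sc,
                            np.random.default_rng(method_seed),
                            guard=config.max_exact_n)
                    err = _score(true_labels, part)
                else:
                    labels = _baseline_labels(method, X, method_seed,
                                              config, informed)
                    err = _score(true_labels, labels)
                rows.append(dict(study="gaussian", method=method, d=d, n=n,
                                 replicate=r, error=err,
                                 wall_time=time.perf_counter() - tic))
    errors = pd.DataFrame(rows)
    table = (errors.groupby(["study", "method", "d", "n"], as_index=False)
             .agg(mean_error=("error", "mean"),
                  se=("error", lambda v: v.std(ddof=1) / np.sqrt(len(v))),
                  replicates=("error", "size"),
                  wall_time=("wall_time", "sum")))
    table.attrs["total_time"] = time.perf_counter() - t0
    return StudyResult(table=table, errors=errors, config=config,
                       seeds={"master": config.seed})


def _sample_granular_set(grid: GranularPriorGrid, theta: float, rho: float,
                         sizes, rng, fixed_counts=False) -> tuple:
    from .granulometry import sample_features
    labels = rng.permutation(np.repeat((1, 2), sizes))
    X = np.empty((labels.size, 4))
    for i, y in enumerate(labels):
        model = grid.grain_model(rho, theta, int(y))
        X[i] = sample_features(model, rng, fixed_counts=fixed_counts)
    return X, labels


def run_granular_study(config: GranularStudyConfig,
                       model: GranularEffectiveModel | None = None) -> StudyResult:
    """Run the granular benchmark: per theta state, ``replicates_per_theta``
    feature sets, all methods on each; aggregate per theta and overall."""
    grid = GranularPriorGrid(
        rho_values=tuple(np.linspace(0.45, 0.55, config.rho_grid)),
        theta_values=tuple(np.linspace(1.75, 2.0, config.theta_grid)),
        n_grains=config.n_grains)
    prior = SizeSpec.fixed(config.sizes)
    master = np.random.SeedSequence(config.seed)
    cov_seed = int(master.generate_state(2)[1] & 0x7FFFFFFF)
    if model is None and "ibr" in config.methods:
        model = GranularEffectiveModel(grid, prior, cov_reps=config.cov_reps,
                                       cov_seed=cov_seed)
    elif model is not None:
        model = model.with_label_prior(prior)
    n = sum(config.sizes)
    engine = ExactIBREngine(n, prior) if "ibr" in config.methods else None
    rows = []
    t0 = time.perf_counter()
    theta_seeds = master.spawn(len(grid.theta_values))
    for t, (theta, theta_seed) in enumerate(zip(grid.theta_values,
                                                theta_seeds)):
        rep_seeds = theta_seed.spawn(config.replicates_per_theta)
        for r, rep_seed in enumerate(rep_seeds):
            data_rng = np.random.default_rng(rep_seed)
            rho = float(data_rng.choice(grid.rho_values))  # redrawn per set
            X, true_labels = _sample_granular_set(
                grid, theta, rho, config.sizes, data_rng,
                fixed_counts=config.fixed_counts)
            method_seed = int(rep_seed.generate_state(1)[0] & 0x7FFFFFFF)
            for method in config.methods:
                tic = time.perf_counter()
                if method == "ibr":
                    part, _, _ = engine.solve(X, model)
                    err = _score(true_labels, part)
                else:
                    labels = _baseline_labels(method, X, method_seed, config)
                    err = _score(true_labels, labels)
                rows.append(dict(study="granular", method=method,
                                 theta=theta, replicate=r, rho=rho,
                                 error=err,
                                 wall_time=time.perf_counter() - tic))
    errors = pd.DataFrame(rows)
    per_theta = (errors.groupby(["study", "method", "theta"], as_index=False)
                 .agg(mean_error=("error", "mean"),
                      se=("error", lambda v: v.std(ddof=1) / np.sqrt(len(v))),
                      replicates=("error", "size"),
                      wall_time=("wall_time", "sum")))
    overall = (errors.groupby(["study", "method"], as_index=False)
               .agg(mean_error=("error", "mean"),
                    se=("error", lambda v: v.std(ddof=1) / np.sqrt(len(v))),
                    replicates=("error", "size"),
                    wall_time=("wall_time", "sum")))
    overall.insert(2, "theta", np.nan)
    table = pd.concat([per_theta, overall], ignore_index=True)
    table.attrs["total_time"] = time.perf_counter() - t0
    return StudyResult(table=table, errors=errors, config=config,
                       seeds={"master": config.seed, "cov": cov_seed})


def emit_results(result: StudyResult, outdir) -> dict:
    """Write the aggregate table, per-replicate errors, and a run log."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"table": out / "results.csv",
             "errors": out / "errors.csv",
             "log": out / "run.log"}
    result.table.to_csv(paths["table"], index=False)
    result.errors.to_csv(paths["errors"], index=False)
    import sklearn
    import scipy
    with open(paths["log"], "w") as fh:
        fh.write(f"config: {result.config!r}\n")
        fh.write(f"seeds: {result.seeds!r}\n")
        fh.write(f"python: {platform.python_version()}\n")
        fh.write(f"numpy: {np.__version__} scipy: {scipy.__version__} "
                 f"pandas: {pd.__version__} sklearn: {sklearn.__version__}\n")
    return paths
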