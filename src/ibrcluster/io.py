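"""Plain-text I/O for point sets, label vectors, and model configs."""

from __future__ import annotations

import numpy as np
import yaml

from .gaussian import GaussianRLPPSpec, NIWParams
from .partitions import SizeSpec


def read_point_set(path) -> np.ndarray:
    """Read an n x d numeric matrix (whitespace or comma delimited)."""
    try:
        X = np.loadtxt(path, ndmin=2)
    except ValueError:
        X = np.loadtxt(path, delimiter=",", ndmin=2)
    if not np.all(np.isfinite(X)):
        raise ValueError("point set contains non-finite entries")
    return X


def write_point_set(path, X) -> None:
    np.savetxt(path, np.atleast_2d(X), fmt="%.10g")


def load_gaussian_spec(path) -> GaussianRLPPSpec:
    """Build a Gaussian RLPP spec from a YAML config.

    Schema::

        sizes: [5, 5]            # fixed per-label counts
        labels:                  # one entry per label (or a single
          - m: [0, 0]            #  entry reused for every label)
            nu: 1.0
            kappa: 4.0
            psi: [[1, 0], [0, 1]]
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    prior = SizeSpec.fixed(cfg["sizes"])
    entries = cfg["labels"]
    if len(entries) == 1:
        entries = entries * prior.n_labels
    niw = tuple(NIWParams(m=np.asarray(e["m"], dtype=float),
                          nu=float(e["nu"]), kappa=float(e["kappa"]),
                          psi=np.asarray(e["psi"], dtype=float))
                for e in entries)
    return GaussianRLPPSpec(niw=niw, label_prior=prior)
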