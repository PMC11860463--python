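"""Seeded two-view synthetic benchmark generator.

Stands in for private multiphase CT feature cohorts: each patient has a
cluster label (e.g. the two levels of a postoperative prognostic
indicator), a shared K-dimensional cluster signal, and two views that
are independent noisy linear images of that signal. The views therefore
carry consistent cluster information plus view-specific noise — exactly
the consistent-and-complementary structure multiview clustering methods
assume.

Difficulty has a closed form: the per-view linear maps have orthonormal
rows, so cluster centroids sit ``separation`` within-cluster standard
deviations apart in every view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import IncompleteMultiviewDataset, MissingSpec, apply_missing
from .errors import ParameterError

_MASK_SEED_STRIDE = 1000003  # derive per-rate mask seeds from the master seed


@dataclass
class SyntheticSpec:
    """Generation parameters for the two-view clustered benchmark.

    separation : centroid distance in units of the within-cluster
        standard deviation (``view_noise``); 0 makes clusters
        exchangeable, 6 (the default benchmark) makes them
        well-separated in each view.
    mixing : optional pair of explicit (K x D_v) view maps; by default a
        seeded random orthonormal-row map per view.
    """

    n_samples: int = 200
    n_clusters: int = 2
    dims: tuple = (20, 24)
    separation: float = 6.0
    view_noise: float = 1.0
    mixing: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ParameterError("n_clusters must be at least 2")
        if self.n_samples < self.n_clusters:
            raise ParameterError(
                f"n_samples ({self.n_samples}) must be >= n_clusters "
                f"({self.n_clusters})"
            )
        if self.separation < 0:
            raise ParameterError("separation must be nonnegative")
        if len(self.dims) != 2:
            raise ParameterError("dims must give exactly two view dimensions")


def _simplex_centroids(k: int, distance: float) -> np.ndarray:
    """K centroids in R^K, all pairwise ``distance`` apart, centered."""
    c = distance / np.sqrt(2.0) * np.eye(k)
    return c - c.mean(axis=0)


def _orthonormal_map(rng: np.random.Generator, k: int, d: int) -> np.ndarray:
    """K x D matrix with orthonormal rows (K <= D), fixed by the rng."""
    q, _ = np.linalg.qr(rng.normal(size=(d, k)))
    return q.T


def generate(spec: SyntheticSpec) -> IncompleteMultiviewDataset:
    """Draw a complete labelled dataset; bit-reproducible given the seed."""
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, spec.n_clusters

    # balanced labels within +-1, order shuffled
    counts = [n // k + (1 if i < n % k else 0) for i in range(k)]
    labels = np.repeat(np.arange(k), counts)
    rng.shuffle(labels)

    centroids = _simplex_centroids(k, spec.separation * spec.view_noise)
    signal = centroids[labels]  # shared K-dim cluster signal

    views = []
    for v, d in enumerate(spec.dims):
        if spec.mixing is not None:
            a = np.asarray(spec.mixing[v], dtype=np.float64)
        else:
            a = _orthonormal_map(rng, k, d)
        noise = spec.view_noise * rng.normal(size=(n, d))
        views.append(signal @ a + noise)

    mask = np.ones((n, 2), dtype=np.int8)
    return IncompleteMultiviewDataset(views=views, mask=mask, labels=labels)


def make_benchmark(spec: SyntheticSpec, rates) -> list:
    """One complete draw, masked once per missing rate.

    All returned datasets share identical underlying features and labels
    and differ only in the availability mask; each rate's mask seed is
    derived deterministically from ``spec.seed`` and the rate's position.
    """
    rates = list(rates)
    if not rates:
        return []
    complete = generate(spec)
    out = []
    for i, rate in enumerate(rates):
        mask_seed = (spec.seed * _MASK_SEED_STRIDE + i + 1) % (2 ** 31)
        out.append(apply_missing(complete, MissingSpec(rate, seed=mask_seed)))
    return out
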