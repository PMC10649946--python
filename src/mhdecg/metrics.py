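"""Similarity metrics between measured and synthesized template sets.

Two complementary views:

* **MMD** (maximum mean discrepancy) compares the *distributions* of two
  sample sets with a Gaussian RBF kernel, using the unbiased-style
  estimator with off-diagonal within-set means and the full cross mean:

      MMD(A, B) = mean_{i!=j} K(a_i, a_j) + mean_{i!=j} K(b_i, b_j)
                  - 2 mean_{i,j} K(a_i, b_j)

  The estimator can be (slightly) negative; values are reported as
  computed, never clamped.

* **DTW** (dynamic time warping) compares two individual traces as the
  minimal sum of *squared* point distances over monotone alignment paths
  anchored at both ends.  No square root is applied to the total.

The Table-style report aggregates per VCG component: one MMD per
component, and DTW as the mean over synthesized templates of the minimum
DTW to any measured template (how close each synthetic template lies to
the measured manifold); alternative aggregation strategies are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

try:  # optional acceleration of the DTW recursion
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap(args[0]) if args and callable(args[0]) else wrap

from .mhd_extraction import TemplateDatabase
from .signal_io import ValidationError

COMPONENTS = ("X", "Y", "Z")


def rbf_kernel_matrix(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * cdist(A, B, "sqeuclidean"))


def median_heuristic_gamma(A: np.ndarray, B: np.ndarray) -> float:
    """gamma = 1 / (2 * median^2) over pairwise distances of the pooled set."""
    pooled = np.vstack([A, B])
    d = cdist(pooled, pooled)
    med = float(np.median(d[np.triu_indices_from(d, k=1)]))
    if med == 0.0:
        return 1.0
    return 1.0 / (2.0 * med ** 2)


def mmd(A: np.ndarray, B: np.ndarray, gamma: float | None = None) -> float:
    """Maximum mean discrepancy between two sample sets (rows = samples)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    n, m = A.shape[0], B.shape[0]
    if n < 2 or m < 2:
        raise ValidationError(f"MMD needs >= 2 samples per set, got {n} and {m}")
    if A.shape[1] != B.shape[1]:
        raise ValidationError(
            f"row-length mismatch: {A.shape[1]} vs {B.shape[1]}")
    if gamma is None:
        gamma = median_heuristic_gamma(A, B)
    Kaa = rbf_kernel_matrix(A, A, gamma)
    Kbb = rbf_kernel_matrix(B, B, gamma)
    Kab = rbf_kernel_matrix(A, B, gamma)
    term_a = (Kaa.sum() - np.trace(Kaa)) / (n * (n - 1))
    term_b = (Kbb.sum() - np.trace(Kbb)) / (m * (m - 1))
    return float(term_a + term_b - 2.0 * Kab.mean())


def dtw(x: np.ndarray, y: np.ndarray) -> float:
    """Dynamic-time-warping dissimilarity: minimal accumulated squared
    Euclidean distance over admissible alignment paths (no square root).

    Accepts univariate traces or multivariate ones (rows = time)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("DTW inputs must be non-empty")
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    cost = cdist(x, y, "sqeuclidean")
    return float(_dtw_accumulate(cost))


@_njit(cache=False)
def _dtw_accumulate(cost: np.ndarray) -> float:
    n, m = cost.shape
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = cost[i - 1, j - 1] + min(acc[i - 1, j - 1],
                                                 acc[i - 1, j],
                                                 acc[i, j - 1])
    return acc[n, m]


@dataclass
class SimilarityReport:
    """Per-component MMD/DTW plus their mean +- standard deviation."""

    mmd_per_component: dict
    dtw_per_component: dict
    mmd_mean: float
    mmd_std: float
    dtw_mean: float
    dtw_std: float
    gamma: dict
    dtw_strategy: str

    def to_dict(self) -> dict:
        return {
            "MMD": {**self.mmd_per_component,
                    "mu": self.mmd_mean, "sigma": self.mmd_std},
            "DTW": {**self.dtw_per_component,
                    "mu": self.dtw_mean, "sigma": self.dtw_std},
            "kernel_gamma": self.gamma,
            "dtw_strategy": self.dtw_strategy,
        }


def _aggregate_dtw(real_traces: np.ndarray, synth_traces: np.ndarray,
                   strategy: str) -> float:
    if strategy == "mean-min":
        mins = [min(dtw(s, r) for r in real_traces) for s in synth_traces]
        return float(np.mean(mins))
    if strategy == "median-median":
        meds = [np.median([dtw(s, r) for r in real_traces])
                for s in synth_traces]
        return float(np.median(meds))
    if strategy == "mean-mean":
        vals = [dtw(s, r) for s in synth_traces for r in real_traces]
        return float(np.mean(vals))
    raise ValidationError(f"unknown DTW aggregation strategy {strategy!r}")


def similarity_report(real: TemplateDatabase, synth: TemplateDatabase,
                      gamma: float | None = None,
                      dtw_strategy: str = "mean-min") -> SimilarityReport:
    """Table-style per-component summary of MMD and DTW between a measured
    and a synthesized template database."""
    if len(real) < 2 or len(synth) < 2:
        raise ValidationError("similarity report needs >= 2 templates per set")
    mmds, dtws, gammas = {}, {}, {}
    for c, name in enumerate(COMPONENTS):
        R = real.component_traces(c)
        S = synth.component_traces(c)
        g = gamma if gamma is not None else median_heuristic_gamma(R, S)
        gammas[name] = g
        mmds[name] = mmd(R, S, g)
        dtws[name] = _aggregate_dtw(R, S, dtw_strategy)
    mv = np.array([mmds[n] for n in COMPONENTS])
    dv = np.array([dtws[n] for n in COMPONENTS])
    return SimilarityReport(
        mmd_per_component=mmds, dtw_per_component=dtws,
        mmd_mean=float(mv.mean()), mmd_std=float(mv.std()),
        dtw_mean=float(dv.mean()), dtw_std=float(dv.std()),
        gamma=gammas, dtw_strategy=dtw_strategy)
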