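"""Subject clustering (Lloyd k-means) and the classification accuracy rate.

k-means is implemented directly: initial means are k distinct points
sampled from the data, observations are assigned to the nearest mean
(squared Euclidean distance, ties toward the lower cluster id), means
are recomputed, and iteration stops when assignments no longer change.
Because a single random initialization is unstable, the best of
``restarts`` seeded initializations (by objective) is returned; set
``restarts=1`` for the single-initialization behaviour.

The accuracy rate matches estimated clusters to true groups by the
bijection maximizing agreement (cluster ids from random initialization
are arbitrary) and reports the matched fraction as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["ClusteringResult", "kmeans", "accuracy_rate"]


@dataclass(frozen=True)
class ClusteringResult:
    """Outcome of one k-means fit (best restart)."""

    assignment: np.ndarray  # observation -> cluster id in 0..k-1
    means: np.ndarray  # k x d centroids
    objective: float  # sum of squared distances to assigned centroids
    iterations: int
    seed: int

    @property
    def k(self) -> int:
        return self.means.shape[0]


def _lloyd(points: np.ndarray, k: int, rng: np.random.Generator):
    n = len(points)
    distinct = np.unique(points, axis=0)
    init_idx = rng.choice(len(distinct), size=k, replace=False)
    means = distinct[init_idx].astype(float)
    assignment = np.full(n, -1, dtype=int)
    for iteration in range(1, 10_000):
        d2 = ((points[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        new_assignment = np.argmin(d2, axis=1)  # argmin ties -> lower cluster id
        if np.array_equal(new_assignment, assignment):
            break
        assignment = new_assignment
        for c in range(k):
            members = points[assignment == c]
            if len(members):
                means[c] = members.mean(axis=0)
    objective = float(((points - means[assignment]) ** 2).sum())
    return assignment, means, objective, iteration


def kmeans(points, k: int, seed: int = 0, restarts: int = 50) -> ClusteringResult:
    """Best-of-``restarts`` Lloyd k-means on an n x d point set."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if points.ndim != 2 or len(points) == 0:
        raise ValueError("points must be a non-empty n x d array")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = len(np.unique(points, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the number of distinct points ({n_distinct})")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    root = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        rng = np.random.default_rng(root.integers(0, 2**63))
        assignment, means, objective, iters = _lloyd(points, k, rng)
        if best is None or objective < best[2] - 1e-15:
            best = (assignment, means, objective, iters)
    return ClusteringResult(
        assignment=best[0], means=best[1], objective=best[2], iterations=best[3],
        seed=seed,
    )


def accuracy_rate(true_groups, est_clusters) -> float:
    """Percentage of observations matched under the best cluster-to-group bijection."""
    true_groups = np.asarray(true_groups)
    est_clusters = np.asarray(est_clusters)
    if true_groups.shape != est_clusters.shape:
        raise ValueError(
            f"labelings differ in size: {true_groups.shape} vs {est_clusters.shape}"
        )
    n = len(true_groups)
    if n == 0:
        raise ValueError("empty labelings")
    t_vals, t_inv = np.unique(true_groups, return_inverse=True)
    e_vals, e_inv = np.unique(est_clusters, return_inverse=True)
    confusion = np.zeros((len(e_vals), len(t_vals)), dtype=int)
    np.add.at(confusion, (e_inv, t_inv), 1)
    rows, cols = linear_sum_assignment(confusion, maximize=True)
    return 100.0 * confusion[rows, cols].sum() / n
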