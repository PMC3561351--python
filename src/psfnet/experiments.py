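"""Threshold-sweep experiments over a cohort of subjects.

Three sweeps over a binarization-threshold grid:

* ``group_q_curve`` — per-subject modularity Q of the detected partition,
  averaged within each group at every threshold;
* ``group_metric_curves`` — same sweep for cost, clustering coefficient,
  local or global efficiency;
* ``classification_sweep`` — per-threshold 2-cluster k-means on the
  per-subject Q values, scored against the true group labels.

Subjects whose binarized network is edgeless at a threshold contribute
value 0 and are flagged rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, community, netbuild
from .synthcohort import SubjectTimeSeries

__all__ = [
    "SweepResult",
    "ClassificationSweepResult",
    "default_grid",
    "build_networks",
    "subject_q_table",
    "group_q_curve",
    "group_metric_curves",
    "classification_sweep",
]

_METRICS = {
    "cost": netbuild.cost,
    "clustering": netbuild.clustering_coefficient,
    "global_efficiency": netbuild.global_efficiency,
    "local_efficiency": netbuild.local_efficiency,
}

# Community counts beyond this are not refined during sweeps; brain-scale
# networks have their modularity optimum at small k.
_SWEEP_K_MAX = 20
_SWEEP_RESTARTS = 2


def default_grid() -> np.ndarray:
    """Binarization thresholds 0.05, 0.10, ..., 0.95."""
    return np.round(np.arange(0.05, 0.951, 0.05), 10)


def _check_grid(grid) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("thresholds must lie in (0, 1)")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    return grid


def build_networks(
    cohort: list[SubjectTimeSeries], method: str = "ps"
) -> list[netbuild.WeightedNetwork]:
    """One weighted network per subject, in cohort order."""
    if method == "ps":
        return [netbuild.build_ps_network(s) for s in cohort]
    if method == "pearson":
        return [netbuild.build_pearson_network(s) for s in cohort]
    raise ValueError(f"method must be 'ps' or 'pearson', got {method!r}")


@dataclass(frozen=True)
class SweepResult:
    """Per-subject and group-mean metric values over a threshold grid."""

    thresholds: np.ndarray
    per_subject: pd.DataFrame  # subject_id, group, threshold, value, flagged
    metric: str
    method: str

    @property
    def per_group_mean(self) -> pd.DataFrame:
        """Group means per threshold (wide: one column per group)."""
        return (
            self.per_subject.pivot_table(
                index="threshold", columns="group", values="value", aggfunc="mean"
            )
            .rename_axis(columns=None)
            .reset_index()
        )

    def write_tsv(self, path: str | Path, summary_path: str | Path | None = None) -> None:
        self.per_subject.to_csv(path, sep="\t", index=False)
        if summary_path is not None:
            self.per_group_mean.to_csv(summary_path, sep="\t", index=False)


def _sweep(cohort, grid, method, value_fn, metric_name) -> SweepResult:
    grid = _check_grid(grid)
    groups = {s.group_label for s in cohort}
    for g in ("case", "control"):
        if sum(s.group_label == g for s in cohort) < 1:
            raise ValueError(f"cohort has no {g} subjects")
    del groups
    networks = build_networks(cohort, method)
    rows = []
    for subj, fw in zip(cohort, networks):
        for t in grid:
            bn = netbuild.binarize(fw, float(t))
            if bn.n_edges == 0:
                value, flagged = 0.0, True
            else:
                value, flagged = value_fn(bn), False
            rows.append(
                (subj.subject_id, subj.group_label, float(t), float(value), flagged)
            )
    per_subject = pd.DataFrame(
        rows, columns=["subject_id", "group", "threshold", "value", "flagged"]
    )
    return SweepResult(
        thresholds=grid, per_subject=per_subject, metric=metric_name, method=method
    )


def subject_q_table(
    cohort: list[SubjectTimeSeries],
    grid,
    method: str = "ps",
    seed: int = 0,
    ds_mode: str = "degree",
) -> pd.DataFrame:
    """Detected-partition modularity per subject per threshold (tidy frame)."""

    def q_of(bn):
        res = community.detect_communities(
            bn, seed=seed, k_max=_SWEEP_K_MAX, restarts=_SWEEP_RESTARTS, ds_mode=ds_mode
        )
        return res.q

    return _sweep(cohort, grid, method, q_of, "q").per_subject


def group_q_curve(
    cohort: list[SubjectTimeSeries],
    grid=None,
    seed: int = 0,
    method: str = "ps",
    q_table: pd.DataFrame | None = None,
) -> SweepResult:
    """Group-averaged modularity of detected communities per threshold.

    Pass a precomputed ``q_table`` (from :func:`subject_q_table`) to share
    per-subject Q values with :func:`classification_sweep`.
    """
    grid = _check_grid(default_grid() if grid is None else grid)
    if q_table is None:
        q_table = subject_q_table(cohort, grid, method=method, seed=seed)
    return SweepResult(thresholds=grid, per_subject=q_table, metric="q", method=method)


def group_metric_curves(
    cohort: list[SubjectTimeSeries],
    grid=None,
    metric: str = "cost",
    method: str = "ps",
) -> SweepResult:
    """Group-averaged graph metric (cost/clustering/efficiencies) per threshold."""
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}, got {metric!r}")
    grid = default_grid() if grid is None else grid
    return _sweep(cohort, grid, method, _METRICS[metric], metric)


@dataclass(frozen=True)
class ClassificationSweepResult:
    """Per-threshold 2-cluster k-means accuracy on the subject Q feature."""

    thresholds: np.ndarray
    accuracy: np.ndarray  # percent, aligned with thresholds
    degenerate: np.ndarray  # True where <2 distinct Q values (no clustering)
    method: str
    q_table: pd.DataFrame

    @property
    def best_threshold(self) -> float:
        return float(self.thresholds[int(np.argmax(self.accuracy))])

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracy.max())

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "threshold": self.thresholds,
                "accuracy_pct": self.accuracy,
                "degenerate": self.degenerate,
            }
        ).to_csv(path, sep="\t", index=False)


def classification_sweep(
    cohort: list[SubjectTimeSeries],
    grid=None,
    method: str = "ps",
    seed: int = 0,
    restarts: int = 50,
    q_table: pd.DataFrame | None = None,
) -> ClassificationSweepResult:
    """k-means (k=2) subject classification from per-threshold Q features.

    At each threshold the scalar Q of every subject feeds a 2-cluster
    k-means; the accuracy rate compares clusters with true group labels
    under the best bijection. Thresholds where all Q values coincide
    cannot be clustered: all subjects fall into one cluster and the
    accuracy is the majority-group fraction (flagged ``degenerate``).
    """
    grid = _check_grid(default_grid() if grid is None else grid)
    if q_table is None:
        q_table = subject_q_table(cohort, grid, method=method, seed=seed)
    labels = {s.subject_id: s.group_label for s in cohort}
    accuracy = np.zeros(len(grid))
    degenerate = np.zeros(len(grid), dtype=bool)
    for idx, t in enumerate(grid):
        sub = q_table[np.isclose(q_table["threshold"], t)]
        q_values = sub["value"].to_numpy()
        true = np.array([labels[sid] for sid in sub["subject_id"]])
        if len(np.unique(q_values)) < 2:
            counts = pd.Series(true).value_counts()
            accuracy[idx] = 100.0 * counts.iloc[0] / len(true)
            degenerate[idx] = True
            continue
        result = classify.kmeans(
            q_values[:, None], k=2, seed=seed + idx, restarts=restarts
        )
        accuracy[idx] = classify.accuracy_rate(true, result.assignment)
    return ClassificationSweepResult(
        thresholds=grid,
        accuracy=accuracy,
        degenerate=degenerate,
        method=method,
        q_table=q_table,
    )
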