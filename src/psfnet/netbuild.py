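"""Per-subject functional networks and binary-graph metrics.

A functional network is an R x R symmetric matrix with zero diagonal:
phase-synchrony degree (entries in [0, 1]) or Pearson correlation
(entries in [-1, 1]). Binarization keeps edges whose weight strictly
exceeds the threshold. Metrics (cost, clustering coefficient, local and
global efficiency) operate on the binary graph; disconnected pairs
contribute zero efficiency (Latora-Marchiori convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .phasesync import DEFAULT_EDGE_TRIM, _as_signal, _interior, analytic_phase

__all__ = [
    "WeightedNetwork",
    "BinaryNetwork",
    "build_ps_network",
    "build_pearson_network",
    "binarize",
    "cost",
    "clustering_coefficient",
    "global_efficiency",
    "local_efficiency",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


def _check_square_symmetric(m: np.ndarray, what: str) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{what} must be square, got shape {m.shape}")
    if m.shape[0] < 2:
        raise ValueError(f"{what} needs at least 2 nodes")
    if not np.allclose(m, m.T):
        raise ValueError(f"{what} must be symmetric")
    if np.any(np.diag(m) != 0):
        raise ValueError(f"{what} must have a zero diagonal")


@dataclass(frozen=True)
class WeightedNetwork:
    """Symmetric weighted connectivity matrix with zero diagonal."""

    weights: np.ndarray
    method: str = "ps"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        _check_square_symmetric(w, "weight matrix")
        if self.method not in ("ps", "pearson"):
            raise ValueError(f"unknown method {self.method!r}")
        off = w[~np.eye(len(w), dtype=bool)]
        if self.method == "ps" and (off.min() < 0 or off.max() > 1):
            raise ValueError("ps weights must lie in [0, 1]")
        if self.method == "pearson" and (off.min() < -1 or off.max() > 1):
            raise ValueError("pearson weights must lie in [-1, 1]")

    @property
    def region_count(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class BinaryNetwork:
    """Unweighted adjacency matrix obtained by thresholding."""

    adjacency: np.ndarray
    threshold: float = field(default=np.nan)

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        a = a.astype(np.int8)
        object.__setattr__(self, "adjacency", a)
        _check_square_symmetric(a, "adjacency matrix")

    @property
    def region_count(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_graph(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        for _, _, d in g.edges(data=True):
            d.clear()
        return g


def _subject_data(subject) -> np.ndarray:
    data = getattr(subject, "data", subject)
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError(f"subject data must be 2-D (regions x time), got {data.shape}")
    if data.shape[0] < 2:
        raise ValueError("subject must have at least 2 regions")
    return data


def build_ps_network(
    subject,
    edge_trim: float = DEFAULT_EDGE_TRIM,
    detrend: str | None = "constant",
) -> WeightedNetwork:
    """Pairwise phase-synchrony degree network of one subject.

    Phases are extracted once per region; the pairwise mean resultant
    lengths are then computed jointly as |Z Z^H| / T over the interior
    samples, where Z holds the unit phasors of each region.
    """
    data = _subject_data(subject)
    n_regions, n_samples = data.shape
    phases = np.empty_like(data)
    for i in range(n_regions):
        try:
            _as_signal(data[i])
            phases[i] = analytic_phase(data[i], detrend).values
        except ValueError as exc:
            raise ValueError(f"region {i + 1}: {exc}") from exc
    sl = _interior(n_samples, edge_trim)
    z = np.exp(1j * phases[:, sl])
    t_eff = z.shape[1]
    w = np.abs(z @ z.conj().T) / t_eff
    np.fill_diagonal(w, 0.0)
    w = np.clip(0.5 * (w + w.T), 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(w, method="ps")


def build_pearson_network(subject, absolute: bool = False) -> WeightedNetwork:
    """Pairwise Pearson-correlation network (signed by default)."""
    data = _subject_data(subject)
    sd = data.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"region {bad[0] + 1}: zero variance, correlation undefined")
    w = np.corrcoef(data)
    if absolute:
        w = np.abs(w)
    np.fill_diagonal(w, 0.0)
    w = np.clip(0.5 * (w + w.T), -1.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(w, method="pearson")


def binarize(network: WeightedNetwork, threshold: float) -> BinaryNetwork:
    """Keep edges with weight strictly greater than ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    a = (network.weights > threshold).astype(np.int8)
    np.fill_diagonal(a, 0)
    return BinaryNetwork(a, threshold=threshold)


def cost(network: BinaryNetwork) -> float:
    """Edge density: edges present / possible edges."""
    r = network.region_count
    return network.n_edges / (r * (r - 1) / 2)


def clustering_coefficient(network: BinaryNetwork) -> float:
    """Node-averaged clustering; degree-<2 nodes contribute 0."""
    return float(nx.average_clustering(network.to_graph(), count_zeros=True))


def global_efficiency(network: BinaryNetwork) -> float:
    """Mean inverse shortest-path length over node pairs (0 if disconnected)."""
    return float(nx.global_efficiency(network.to_graph()))


def local_efficiency(network: BinaryNetwork) -> float:
    """Mean over nodes of the global efficiency of the neighbor subgraph."""
    return float(nx.local_efficiency(network.to_graph()))


def write_matrix_tsv(matrix: np.ndarray, path: str | Path, fmt: str = "%.6f") -> None:
    """Dense TSV with a header row of 1-based region indices."""
    m = np.asarray(matrix)
    header = "\t".join(str(i + 1) for i in range(m.shape[1]))
    np.savetxt(path, m, fmt=fmt, delimiter="\t", header=header, comments="")


def read_matrix_tsv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", skiprows=1)
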