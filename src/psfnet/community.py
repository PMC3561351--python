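"""Community structure: modularity, detection, and node-role analysis.

Modularity of a partition of a binary network is

    Q = sum_s ( l_s / L  -  (d_s / 2L)^2 )

with L the total edge count, l_s the number of edges inside community s
and d_s the degree sum of its nodes (``ds_mode="degree"``). A literal
variant where the penalty uses the fraction of edges with at least one
endpoint in s is available as ``ds_mode="incident"``.

Detection greedily merges communities by best modularity gain, recording
the best Q at every intermediate community count (the Q-vs-k curve),
then refines each intermediate partition by seeded local node moves.
Isolated nodes are excluded from detection and parked in a sentinel
community.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .netbuild import BinaryNetwork

__all__ = [
    "Partition",
    "NodeRoleProfile",
    "RoleThresholds",
    "DetectionResult",
    "modularity",
    "detect_communities",
    "exhaustive_max_modularity",
    "within_degree_zscore",
    "inter_community_ratio",
    "classify_roles",
    "node_roles",
    "write_roles_tsv",
]

_ROLE_NAMES = ("T1", "T2", "T3", "T4", "T5", "T6")
_EXHAUSTIVE_MAX_N = 10


@dataclass(frozen=True)
class Partition:
    """Community assignment: ``labels[i]`` is the community id (1..k) of node i."""

    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1 or len(labels) == 0:
            raise ValueError("labels must be a non-empty 1-D array")
        present = np.unique(labels)
        if present[0] != 1 or not np.array_equal(present, np.arange(1, len(present) + 1)):
            raise ValueError("community ids must be contiguous 1..k with no empty community")

    @property
    def k(self) -> int:
        return int(self.labels.max())

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def communities(self) -> list[np.ndarray]:
        """Member node indices (0-based) of communities 1..k, in id order."""
        return [np.flatnonzero(self.labels == c) for c in range(1, self.k + 1)]

    @staticmethod
    def from_labels(raw) -> "Partition":
        """Relabel arbitrary community labels to contiguous ids 1..k."""
        raw = np.asarray(raw)
        _, inv = np.unique(raw, return_inverse=True)
        return Partition(inv + 1)

    def write_tsv(self, path: str | Path) -> None:
        lines = ["node\tcommunity"]
        lines += [f"{i + 1}\t{c}" for i, c in enumerate(self.labels)]
        Path(path).write_text("\n".join(lines) + "\n")


def _adjacency(network) -> np.ndarray:
    a = network.adjacency if isinstance(network, BinaryNetwork) else np.asarray(network)
    return a.astype(int)


def modularity(network, partition: Partition, ds_mode: str = "degree") -> float:
    """Modularity Q of ``partition`` on a binary network."""
    if ds_mode not in ("degree", "incident"):
        raise ValueError(f"ds_mode must be 'degree' or 'incident', got {ds_mode!r}")
    a = _adjacency(network)
    if len(partition.labels) != a.shape[0]:
        raise ValueError("partition size does not match network")
    total = a.sum() / 2
    if total == 0:
        raise ValueError("modularity undefined for an edgeless network")
    deg = a.sum(axis=1)
    q = 0.0
    for members in partition.communities():
        sub = a[np.ix_(members, members)]
        l_s = sub.sum() / 2
        if ds_mode == "degree":
            d_s = deg[members].sum()
            q += l_s / total - (d_s / (2 * total)) ** 2
        else:
            incident = deg[members].sum() - l_s  # edges with >=1 endpoint in s
            q += l_s / total - (incident / total) ** 2
    return float(q)


def _merge_gain_matrix(e, l_s, d_s, m_s, total, alive, ds_mode):
    """Pairwise modularity gain for merging communities (vectorized)."""
    if ds_mode == "degree":
        gain = e / total - np.outer(d_s, d_s) / (2.0 * total**2)
    else:
        merged = m_s[:, None] + m_s[None, :] - e
        gain = e / total - (merged**2 - m_s[:, None] ** 2 - m_s[None, :] ** 2) / total**2
    mask = np.outer(alive, alive)
    np.fill_diagonal(mask, False)
    gain[~mask] = -np.inf
    return gain


def _pick_best_pair(gain, e, rng, explore):
    """Best-gain pair, preferring connected pairs; seeded tie-break.

    With ``explore``, occasionally merges one of the top-3 candidates
    instead of the single best, diversifying restarts beyond tie-breaks.
    """
    for candidates in (gain.copy(), None):
        g = gain if candidates is None else candidates
        if candidates is not None:
            g[e <= 0] = -np.inf
        best = g.max()
        if not np.isfinite(best):
            continue
        if explore and rng.uniform() < 0.35:
            flat = g.ravel()
            top = np.argsort(flat)[-3:]
            top = top[np.isfinite(flat[top])]
            idx = int(top[rng.integers(len(top))])
            return idx // g.shape[0], idx % g.shape[0]
        ties = np.argwhere(np.isclose(g, best, rtol=0, atol=1e-12))
        a, b = ties[rng.integers(len(ties))]
        return int(a), int(b)
    raise RuntimeError("no mergeable pair found")  # pragma: no cover


def _greedy_merge(a, rng, ds_mode, explore=False):
    """Agglomerative pass; returns {k: (labels, Q)} snapshots."""
    n = a.shape[0]
    total = a.sum() / 2
    deg = a.sum(axis=1).astype(float)
    labels = np.arange(n)
    e = a.astype(float).copy()
    l_s = np.zeros(n)
    d_s = deg.copy()
    m_s = deg.copy()  # edges with >=1 endpoint in a singleton = its degree
    alive = np.ones(n, dtype=bool)
    if ds_mode == "degree":
        q = -float(np.sum((deg / (2 * total)) ** 2))
    else:
        q = -float(np.sum((deg / total) ** 2))
    snapshots = {n: (labels.copy(), q)}
    for k in range(n - 1, 0, -1):
        gain = _merge_gain_matrix(e, l_s, d_s, m_s, total, alive, ds_mode)
        ia, ib = _pick_best_pair(gain, e, rng, explore)
        q += gain[ia, ib]
        l_s[ia] += l_s[ib] + e[ia, ib]
        d_s[ia] += d_s[ib]
        m_s[ia] += m_s[ib] - e[ia, ib]
        e[ia, :] += e[ib, :]
        e[:, ia] += e[:, ib]
        e[ia, ia] = 0.0
        alive[ib] = False
        labels[labels == ib] = ia
        snapshots[k] = (labels.copy(), q)
    return snapshots


def _move_gain(a, labels, i, cb, total, deg, d_s):
    """Degree-mode Q gain of moving node i to community cb."""
    ca = labels[i]
    nbrs = np.flatnonzero(a[i])
    k_ia = float(np.count_nonzero(labels[nbrs] == ca))
    k_ib = float(np.count_nonzero(labels[nbrs] == cb))
    ki = deg[i]
    return (k_ib - k_ia) / total - ki * (d_s[cb] - d_s[ca] + ki) / (2.0 * total**2)


def _apply_move(labels, i, cb, deg, d_s, size):
    ca = labels[i]
    labels[i] = cb
    d_s[ca] -= deg[i]
    d_s[cb] += deg[i]
    size[ca] -= 1
    size[cb] += 1


def _greedy_pass(a, labels, rng, total, deg, d_s, size, comms):
    """One hill-climbing sweep of single node moves; True if anything moved."""
    moved = False
    for i in rng.permutation(len(labels)):
        ca = labels[i]
        if size[ca] == 1:
            continue
        best_gain, best_c = 1e-12, None
        for cb in comms:
            if cb == ca:
                continue
            gain = _move_gain(a, labels, i, cb, total, deg, d_s)
            if gain > best_gain:
                best_gain, best_c = gain, cb
        if best_c is not None:
            _apply_move(labels, i, best_c, deg, d_s, size)
            moved = True
    return moved


def _kl_pass(a, labels, rng, total, deg, d_s, size, comms):
    """Kernighan-Lin escape: chain best moves (each node once, possibly
    negative), keep the best prefix. True if the prefix improves Q."""
    n = len(labels)
    done = np.zeros(n, dtype=bool)
    seq: list[tuple[int, int, int]] = []  # (node, from, to)
    cum = best_cum = 0.0
    best_len = 0
    for _ in range(n):
        best = None
        for i in rng.permutation(n):
            if done[i]:
                continue
            ca = labels[i]
            if size[ca] == 1:
                continue
            for cb in comms:
                if cb == ca:
                    continue
                gain = _move_gain(a, labels, i, cb, total, deg, d_s)
                if best is None or gain > best[0]:
                    best = (gain, i, cb)
        if best is None:
            break
        gain, i, cb = best
        ca = labels[i]
        _apply_move(labels, i, cb, deg, d_s, size)
        done[i] = True
        seq.append((i, ca, cb))
        cum += gain
        if cum > best_cum + 1e-12:
            best_cum, best_len = cum, len(seq)
    for i, ca, _cb in reversed(seq[best_len:]):  # roll back past the best prefix
        _apply_move(labels, i, ca, deg, d_s, size)
    return best_len > 0


def _refine_degree(a, labels, rng, max_rounds=50):
    """Local node moves (fixed community count) maximizing degree-mode Q.

    Alternates hill-climbing sweeps with Kernighan-Lin chains that can
    cross Q valleys a single move cannot.
    """
    total = a.sum() / 2
    deg = a.sum(axis=1).astype(float)
    labels = labels.copy()
    comms = list(np.unique(labels))
    d_s = {c: deg[labels == c].sum() for c in comms}
    size = {c: int((labels == c).sum()) for c in comms}
    use_kl = len(labels) <= 48  # KL chains are O(n^2 k) per step
    for _ in range(max_rounds):
        if _greedy_pass(a, labels, rng, total, deg, d_s, size, comms):
            continue
        if not (use_kl and _kl_pass(a, labels, rng, total, deg, d_s, size, comms)):
            break
    return labels


def _refine_incident(a, labels, rng, max_passes=20):
    """Local node moves for incident-mode Q (full recompute; small graphs)."""
    labels = labels.copy()
    comms = np.unique(labels)
    size = {c: int((labels == c).sum()) for c in comms}
    best_q = modularity(a, Partition.from_labels(labels), ds_mode="incident")
    nodes = np.arange(len(labels))
    for _ in range(max_passes):
        moved = False
        for i in rng.permutation(nodes):
            ca = labels[i]
            if size[ca] == 1:
                continue
            for cb in comms:
                if cb == ca:
                    continue
                labels[i] = cb
                q = modularity(a, Partition.from_labels(labels), ds_mode="incident")
                if q > best_q + 1e-12:
                    best_q = q
                    size[ca] -= 1
                    size[cb] += 1
                    ca = cb
                    moved = True
                else:
                    labels[i] = ca
        if not moved:
            break
    return labels


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of modularity maximization."""

    partition: Partition
    q: float
    curve: dict[int, float]
    isolated: tuple[int, ...] = ()

    def write_curve_tsv(self, path: str | Path) -> None:
        lines = ["n_communities\tq_max"]
        lines += [f"{k}\t{self.curve[k]:.6f}" for k in sorted(self.curve)]
        Path(path).write_text("\n".join(lines) + "\n")


def detect_communities(
    network,
    seed: int = 0,
    k_max: int | None = None,
    restarts: int = 8,
    ds_mode: str = "degree",
) -> DetectionResult:
    """Modularity maximization by greedy merging plus node-move refinement.

    Returns the best partition found, its Q, and the Q-vs-community-count
    curve (best refined Q at each candidate count 1..k_max over all
    restarts). Deterministic given ``seed``.
    """
    if ds_mode not in ("degree", "incident"):
        raise ValueError(f"ds_mode must be 'degree' or 'incident', got {ds_mode!r}")
    a_full = _adjacency(network)
    n_full = a_full.shape[0]
    deg_full = a_full.sum(axis=1)
    active = np.flatnonzero(deg_full > 0)
    isolated = tuple(int(i) for i in np.flatnonzero(deg_full == 0))
    if len(active) == 0:
        raise ValueError("community detection undefined for an edgeless network")
    a = a_full[np.ix_(active, active)]
    n = len(active)
    if k_max is None:
        k_max = n
    k_max = min(k_max, n)

    refine = _refine_degree if ds_mode == "degree" else _refine_incident
    curve: dict[int, float] = {}
    best_q = -np.inf
    best_labels = None
    rng = np.random.default_rng(seed)
    for restart in range(max(1, restarts)):
        snapshots = _greedy_merge(a, rng, ds_mode, explore=restart > 0)
        for k in range(1, k_max + 1):
            labels_k, _ = snapshots[k]
            if k > 1:
                labels_k = refine(a, labels_k, rng)
            part_k = Partition.from_labels(labels_k)
            q_k = modularity(a, part_k, ds_mode=ds_mode)
            if q_k > curve.get(k, -np.inf):
                curve[k] = q_k
            if q_k > best_q + 1e-12 or (
                q_k > best_q - 1e-12 and best_labels is not None
                and part_k.k < Partition.from_labels(best_labels).k
            ):
                best_q = q_k
                best_labels = part_k.labels

    labels_full = np.zeros(n_full, dtype=int)
    labels_full[active] = best_labels
    k_found = int(best_labels.max())
    if isolated:
        labels_full[list(isolated)] = k_found + 1
    partition = Partition(labels_full)
    return DetectionResult(partition=partition, q=float(best_q), curve=curve,
                           isolated=isolated)


def _set_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    labels = np.zeros(n, dtype=int)

    def rec(i, max_label):
        if i == n:
            yield labels.copy()
            return
        for c in range(max_label + 2):
            labels[i] = c
            yield from rec(i + 1, max(max_label, c))

    yield from rec(1, 0)


def exhaustive_max_modularity(network, ds_mode: str = "degree") -> tuple[Partition, float]:
    """Brute-force maximum-modularity partition over all set partitions.

    Intended as a testing oracle; limited to small graphs (n <= 10)
    because the Bell number explodes.
    """
    a = _adjacency(network)
    n = a.shape[0]
    if n > _EXHAUSTIVE_MAX_N:
        raise ValueError(f"exhaustive search limited to n <= {_EXHAUSTIVE_MAX_N}")
    best_q, best = -np.inf, None
    for labels in _set_partitions(n):
        part = Partition.from_labels(labels)
        q = modularity(a, part, ds_mode=ds_mode)
        if q > best_q:
            best_q, best = q, part
    return best, float(best_q)


def within_degree_zscore(network, partition: Partition, ddof: int = 0) -> np.ndarray:
    """Within-community degree z-score per node; z = 0 where the community
    intra-degree spread is zero (population sd by default)."""
    a = _adjacency(network)
    z = np.zeros(a.shape[0])
    for members in partition.communities():
        kappa = a[np.ix_(members, members)].sum(axis=1).astype(float)
        sd = kappa.std(ddof=ddof) if len(kappa) > ddof else 0.0
        if sd > 0:
            z[members] = (kappa - kappa.mean()) / sd
    return z


def inter_community_ratio(network, partition: Partition) -> np.ndarray:
    """Fraction of each node's degree leaving its community; 0 for isolated nodes."""
    a = _adjacency(network)
    deg = a.sum(axis=1).astype(float)
    r = np.zeros(a.shape[0])
    for members in partition.communities():
        kappa = a[np.ix_(members, members)].sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ri = np.where(deg[members] > 0, (deg[members] - kappa) / deg[members], 0.0)
        r[members] = ri
    return r


@dataclass(frozen=True)
class RoleThresholds:
    """Cutoffs splitting the (z, r) plane into the six role classes."""

    z_c: float = 1.0
    r_lo: float = 0.3
    r_hi: float = 0.7

    def __post_init__(self):
        if not 0.0 <= self.r_lo < self.r_hi <= 1.0:
            raise ValueError("require 0 <= r_lo < r_hi <= 1")


@dataclass(frozen=True)
class NodeRoleProfile:
    node: int
    z: float
    r: float
    role: str


def classify_roles(
    z: np.ndarray,
    r: np.ndarray,
    thresholds: RoleThresholds = RoleThresholds(),
) -> list[NodeRoleProfile]:
    """Assign each node one of the six roles from its (z, r) coordinates.

    Hubs have z >= z_c. The r-axis splits into local [0, r_lo),
    transfer [r_lo, r_hi) and backbone [r_hi, 1] bands:
    T1/T2/T3 = backbone/transfer/local hubs, T4/T5/T6 the non-hub bands.
    """
    z = np.asarray(z, dtype=float)
    r = np.asarray(r, dtype=float)
    if z.shape != r.shape:
        raise ValueError("z and r must have the same shape")
    profiles = []
    for i, (zi, ri) in enumerate(zip(z, r)):
        hub = zi >= thresholds.z_c
        if ri >= thresholds.r_hi:
            band = 0  # backbone
        elif ri >= thresholds.r_lo:
            band = 1  # transfer
        else:
            band = 2  # local
        role = _ROLE_NAMES[band if hub else band + 3]
        profiles.append(NodeRoleProfile(node=i + 1, z=float(zi), r=float(ri), role=role))
    return profiles


def node_roles(
    network,
    partition: Partition,
    thresholds: RoleThresholds = RoleThresholds(),
) -> list[NodeRoleProfile]:
    """Convenience: z, r and role class for every node of a partitioned network."""
    z = within_degree_zscore(network, partition)
    r = inter_community_ratio(network, partition)
    return classify_roles(z, r, thresholds)


def write_roles_tsv(profiles: list[NodeRoleProfile], path: str | Path) -> None:
    lines = ["node\tz\tr\trole"]
    lines += [f"{p.node}\t{p.z:.6f}\t{p.r:.6f}\t{p.role}" for p in profiles]
    Path(path).write_text("\n".join(lines) + "\n")
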