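import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psfnet import community
from psfnet.community import (
    NodeRoleProfile,
    Partition,
    RoleThresholds,
    classify_roles,
    detect_communities,
    exhaustive_max_modularity,
    inter_community_ratio,
    modularity,
    node_roles,
    within_degree_zscore,
)


def edges_to_adjacency(n, edges):
    a = np.zeros((n, n), dtype=int)
    for u, v in edges:
        a[u, v] = a[v, u] = 1
    return a


def two_triangles():
    return edges_to_adjacency(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


def random_connected(rng, n_lo=4, n_hi=9):
    n = int(rng.integers(n_lo, n_hi))
    while True:
        g = nx.gnp_random_graph(n, float(rng.uniform(0.3, 0.8)),
                                seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and g.number_of_edges() > 0:
            return nx.to_numpy_array(g).astype(int)


class TestPartition:
    def test_valid(self):
        p = Partition(np.array([1, 1, 2, 3, 3]))
        assert p.k == 3
        assert [list(c) for c in p.communities()] == [[0, 1], [2], [3, 4]]

    def test_noncontiguous_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            Partition(np.array([1, 3]))

    def test_from_labels_relabels(self):
        p = Partition.from_labels(["b", "a", "b", "c"])
        assert p.k == 3
        assert len(set(map(tuple, (list(c) for c in p.communities())))) == 3


class TestModularity:
    def test_single_community_is_zero(self):
        a = two_triangles()
        assert modularity(a, Partition(np.ones(6, dtype=int))) == pytest.approx(0.0)

    def test_two_triangles(self):
        q = modularity(two_triangles(), Partition(np.array([1, 1, 1, 2, 2, 2])))
        assert q == pytest.approx(0.5)

    def test_newman_form_oracle(self, rng):
        # oracle: Q = (1/2L) sum_ij (A_ij - d_i d_j / 2L) delta(c_i, c_j)
        for _ in range(20):
            a = random_connected(rng)
            n = a.shape[0]
            labels = rng.integers(1, 4, size=n)
            p = Partition.from_labels(labels)
            L2 = a.sum()
            d = a.sum(axis=1)
            same = p.labels[:, None] == p.labels[None, :]
            q_oracle = ((a - np.outer(d, d) / L2) * same).sum() / L2
            assert modularity(a, p) == pytest.approx(q_oracle, abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(20):
            a = random_connected(rng)
            labels = rng.integers(1, 4, size=a.shape[0])
            q = modularity(a, Partition.from_labels(labels))
            assert -1.0 <= q < 1.0

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError, match="edgeless"):
            modularity(np.zeros((3, 3), int), Partition(np.ones(3, dtype=int)))

    def test_incident_mode_two_triangles(self):
        q = modularity(two_triangles(), Partition(np.array([1, 1, 1, 2, 2, 2])),
                       ds_mode="incident")
        assert q == pytest.approx(0.5)  # no inter-community edges: modes agree


class TestDetect:
    def test_two_disjoint_cliques(self):
        a = np.zeros((8, 8), int)
        a[:4, :4] = 1 - np.eye(4, dtype=int)
        a[4:, 4:] = 1 - np.eye(4, dtype=int)
        res = detect_communities(a, seed=0)
        assert res.q == pytest.approx(0.5)
        assert res.partition.k == 2
        assert len(set(res.partition.labels[:4])) == 1
        assert len(set(res.partition.labels[4:])) == 1

    def test_complete_graph_single_community(self):
        a = np.ones((7, 7), int) - np.eye(7, dtype=int)
        _, q_star = exhaustive_max_modularity(a)
        res = detect_communities(a, seed=0)
        assert res.q == pytest.approx(q_star)
        assert res.q <= 0.0 + 1e-12
        assert res.partition.k == 1

    def test_ring_of_triangles(self):
        edges = []
        for t in range(4):
            base = 3 * t
            edges += [(base, base + 1), (base + 1, base + 2), (base, base + 2)]
        edges += [(2, 3), (5, 6), (8, 9), (11, 0)]
        res = detect_communities(edges_to_adjacency(12, edges), seed=0)
        assert res.partition.k == 4
        for t in range(4):
            assert len(set(res.partition.labels[3 * t: 3 * t + 3])) == 1

    def test_matches_exhaustive_on_random_graphs(self, rng):
        for trial in range(30):
            a = random_connected(rng)
            _, q_star = exhaustive_max_modularity(a)
            res = detect_communities(a, seed=trial)
            assert res.q == pytest.approx(q_star, abs=1e-10)

    def test_never_below_single_community(self, rng):
        for trial in range(10):
            a = random_connected(rng)
            res = detect_communities(a, seed=trial)
            assert res.q >= -1e-12

    def test_curve_contains_all_k(self):
        a = two_triangles()
        res = detect_communities(a, seed=0)
        assert set(res.curve) == set(range(1, 7))
        assert res.curve[1] == pytest.approx(0.0)
        assert max(res.curve.values()) == pytest.approx(res.q)

    def test_deterministic(self):
        a = random_connected(np.random.default_rng(5))
        r1 = detect_communities(a, seed=3)
        r2 = detect_communities(a, seed=3)
        assert np.array_equal(r1.partition.labels, r2.partition.labels)
        assert r1.q == r2.q
        assert r1.curve == r2.curve

    def test_isolated_nodes_sentinel(self):
        a = np.zeros((8, 8), int)
        a[:3, :3] = 1 - np.eye(3, dtype=int)
        a[3:6, 3:6] = 1 - np.eye(3, dtype=int)
        res = detect_communities(a, seed=0)
        assert res.isolated == (6, 7)
        sentinel = res.partition.labels[6]
        assert res.partition.labels[7] == sentinel
        assert sentinel == res.partition.k

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError, match="edgeless"):
            detect_communities(np.zeros((4, 4), int), seed=0)

    def test_planted_modules_exceed_significance_level(self, rng):
        # two dense planted modules, sparse between: Q > 0.3 heuristic
        for trial in range(2):
            n = 20
            a = np.zeros((n, n), int)
            for i, j in itertools.combinations(range(n), 2):
                same = (i < 10) == (j < 10)
                p = 0.85 if same else 0.05
                if rng.uniform() < p:
                    a[i, j] = a[j, i] = 1
            res = detect_communities(a, seed=trial)
            assert res.q > 0.3


class TestNodeRoles:
    def test_clique_community_zero_z(self):
        a = np.ones((5, 5), int) - np.eye(5, dtype=int)
        z = within_degree_zscore(a, Partition(np.ones(5, dtype=int)))
        assert np.allclose(z, 0.0)

    def test_star_community_center_z(self):
        star = np.zeros((4, 4), int)
        star[0, 1:] = star[1:, 0] = 1
        z = within_degree_zscore(star, Partition(np.ones(4, dtype=int)))
        assert z[0] == pytest.approx(1.5 / np.sqrt(0.75))  # ~1.732, population sd

    def test_zscore_normalization(self, rng):
        for _ in range(10):
            a = random_connected(rng, 6, 10)
            res = detect_communities(a, seed=0)
            z = within_degree_zscore(a, res.partition)
            for members in res.partition.communities():
                kappa = a[np.ix_(members, members)].sum(axis=1)
                if kappa.std() > 0:
                    assert np.mean(z[members]) == pytest.approx(0.0, abs=1e-12)
                    assert np.std(z[members]) == pytest.approx(1.0, abs=1e-12)

    def test_inter_ratio_endpoints(self):
        # node 0: all links internal; node 3: all links external
        a = edges_to_adjacency(4, [(0, 1), (1, 2), (0, 2), (2, 3)])
        p = Partition(np.array([1, 1, 1, 2]))
        r = inter_community_ratio(a, p)
        assert r[0] == 0.0
        assert r[3] == 1.0

    def test_inter_ratio_half(self):
        edges = [(0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (3, 4)]
        a = edges_to_adjacency(5, edges)
        p = Partition(np.array([1, 1, 1, 2, 2]))
        assert inter_community_ratio(a, p)[0] == pytest.approx(0.5)

    def test_role_examples(self):
        th = RoleThresholds()
        (hub_backbone,) = classify_roles([th.z_c + 1], [th.r_hi + 0.01], th)
        assert hub_backbone.role == "T1"
        (local_nonhub,) = classify_roles([th.z_c - 1], [0.0], th)
        assert local_nonhub.role == "T6"

    @given(
        z=st.floats(-5, 5),
        r=st.floats(0, 1),
        z_c=st.floats(-1, 3),
        r_lo=st.floats(0.05, 0.45),
        r_hi=st.floats(0.5, 0.95),
    )
    @settings(max_examples=50, deadline=None)
    def test_roles_partition_the_plane(self, z, r, z_c, r_lo, r_hi):
        th = RoleThresholds(z_c=z_c, r_lo=r_lo, r_hi=r_hi)
        (profile,) = classify_roles([z], [r], th)
        assert profile.role in {"T1", "T2", "T3", "T4", "T5", "T6"}
        hub = z >= z_c
        band = 0 if r >= r_hi else (1 if r >= r_lo else 2)
        expected = ("T1", "T2", "T3")[band] if hub else ("T4", "T5", "T6")[band]
        assert profile.role == expected

    def test_role_invariance_under_relabeling(self, rng):
        a = random_connected(rng, 8, 10)
        res = detect_communities(a, seed=1)
        labels = res.partition.labels
        k = res.partition.k
        perm = rng.permutation(k) + 1
        relabeled = Partition.from_labels(perm[labels - 1])
        p1 = node_roles(a, res.partition)
        p2 = node_roles(a, relabeled)
        assert [x.role for x in p1] == [x.role for x in p2]
        assert [x.z for x in p1] == pytest.approx([x.z for x in p2])

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            RoleThresholds(r_lo=0.8, r_hi=0.3)


def test_roles_tsv(tmp_path):
    profiles = [NodeRoleProfile(1, 1.2, 0.4, "T2"), NodeRoleProfile(2, -0.5, 0.1, "T6")]
    path = tmp_path / "roles.tsv"
    community.write_roles_tsv(profiles, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "node\tz\tr\trole"
    assert lines[1].endswith("T2")
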