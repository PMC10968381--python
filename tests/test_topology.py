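import itertools

import networkx as nx
import numpy as np
import pytest

from alphanet import connectivity, synth, topology
from alphanet.spectral import ALPHA


def cm_from(matrix, labels):
    return connectivity.ConnectivityMatrix(values=np.asarray(matrix, float),
                                           band=ALPHA, n_epochs=1,
                                           channel_labels=list(labels))


def random_weighted_matrix(rng, n):
    m = rng.uniform(0.05, 1.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


# ---------------------------------------------------------------------------
# brute-force oracles (independent of networkx and of the implementation)


def floyd_warshall(dist):
    d = dist.copy()
    n = d.shape[0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    return d


def oracle_local_efficiency(adj):
    """Weighted local efficiency via explicit Floyd-Warshall on each
    neighbor subgraph; weights pre-normalized to max 1, lengths 1/w."""
    n = adj.shape[0]
    wmax = adj.max() if adj.max() > 0 else 1.0
    w = adj / wmax
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i] > 0)
        k = len(nbrs)
        if k < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        dist = np.where(sub > 0, 1.0 / np.where(sub > 0, sub, 1.0), np.inf)
        np.fill_diagonal(dist, 0.0)
        d = floyd_warshall(dist)
        total = sum(1.0 / d[a, b] for a in range(k) for b in range(k)
                    if a != b and np.isfinite(d[a, b]))
        out[i] = total / (k * (k - 1))
    return out


def oracle_clustering(adj):
    """Onnela weighted clustering by direct triangle summation."""
    n = adj.shape[0]
    wmax = adj.max() if adj.max() > 0 else 1.0
    w = adj / wmax
    out = np.zeros(n)
    for i in range(n):
        k = int(np.sum(adj[i] > 0))
        if k < 2:
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    s += (w[i, j] * w[j, h] * w[i, h]) ** (1.0 / 3.0)
        out[i] = s / (k * (k - 1))
    return out


def oracle_betweenness(adj):
    """Exhaustive shortest-path enumeration with 1/w lengths."""
    n = adj.shape[0]
    wmax = adj.max() if adj.max() > 0 else 1.0
    w = adj / wmax
    nodes = range(n)
    bc = np.zeros(n)
    for s, t in itertools.combinations(nodes, 2):
        best = np.inf
        best_paths = []
        for r in range(n - 1):
            for mid in itertools.permutations([v for v in nodes if v not in (s, t)], r):
                path = (s, *mid, t)
                ok = all(adj[a, b] > 0 for a, b in zip(path, path[1:]))
                if not ok:
                    continue
                length = sum(1.0 / w[a, b] for a, b in zip(path, path[1:]))
                if length < best - 1e-12:
                    best, best_paths = length, [path]
                elif abs(length - best) <= 1e-12:
                    best_paths.append(path)
        for path in best_paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(best_paths)
    return bc


# ---------------------------------------------------------------------------


class TestProportionalThreshold:
    def test_top_edges_retained(self, rng):
        m = np.zeros((4, 4))
        vals = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
        iu = np.triu_indices(4, 1)
        m[iu] = vals
        m = m + m.T
        tg = topology.proportional_threshold(cm_from(m, "abcd"), 0.5)
        kept = {frozenset(e) for e in tg.graph.edges}
        assert tg.graph.number_of_edges() == 3
        assert kept == {frozenset("ab"), frozenset("ac"), frozenset("ad")}

    def test_full_sparsity_complete_graph(self, rng):
        m = random_weighted_matrix(rng, 6)
        tg = topology.proportional_threshold(cm_from(m, "abcdef"), 1.0)
        assert tg.graph.number_of_edges() == 15

    def test_default_grid_is_ten_thresholds(self):
        assert len(topology.DEFAULT_SPARSITIES) == 10
        np.testing.assert_allclose(topology.DEFAULT_SPARSITIES,
                                   np.arange(1, 11) * 0.05)

    def test_nested_across_sparsities(self, rng):
        m = random_weighted_matrix(rng, 12)
        cm = cm_from(m, [f"n{i}" for i in range(12)])
        prev = set()
        for s in topology.DEFAULT_SPARSITIES:
            edges = {frozenset(e) for e in
                     topology.proportional_threshold(cm, s).graph.edges}
            assert prev <= edges
            prev = edges

    def test_tie_break_deterministic(self):
        m = np.full((4, 4), 0.5)
        np.fill_diagonal(m, 0.0)
        a = topology.proportional_threshold(cm_from(m, "abcd"), 0.5)
        b = topology.proportional_threshold(cm_from(m, "abcd"), 0.5)
        assert sorted(a.graph.edges) == sorted(b.graph.edges)

    def test_out_of_range_sparsity_rejected(self, rng):
        cm = cm_from(random_weighted_matrix(rng, 4), "abcd")
        for s in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                topology.proportional_threshold(cm, s)


class TestClosedForms:
    def test_complete_k4_unit_weights(self):
        m = np.ones((4, 4)) - np.eye(4)
        tg = topology.proportional_threshold(cm_from(m, "abcd"), 1.0)
        assert topology.clustering_coefficient(tg)[1] == pytest.approx(1.0)
        assert topology.local_efficiency(tg)[1] == pytest.approx(1.0)

    def test_path_p4_no_triangles(self):
        m = np.zeros((4, 4))
        for i in range(3):
            m[i, i + 1] = m[i + 1, i] = 1.0
        tg = topology.proportional_threshold(cm_from(m, "abcd"), 0.5)
        assert topology.clustering_coefficient(tg)[1] == 0.0

    def test_star_center_betweenness_and_hub(self):
        m = np.zeros((5, 5))
        m[0, 1:] = m[1:, 0] = 1.0
        tg = topology.proportional_threshold(cm_from(m, "abcde"), 0.4)
        bc = topology.betweenness(tg)
        assert bc["a"] == pytest.approx(6.0)  # C(4,2) pairs through the center
        assert all(bc[v] == 0.0 for v in "bcde")
        assert topology.identify_hubs(bc).hubs == ["a"]
        assert topology.local_efficiency(tg)[1] == 0.0  # neighbor sets edgeless

    def test_onnela_triangle_with_half_weight_edge(self):
        """Direct evaluation: the single triangle product is (1*1*0.5)^(1/3)
        for every node."""
        m = np.array([[0, 1, 1], [1, 0, 0.5], [1, 0.5, 0]], float)
        tg = topology.proportional_threshold(cm_from(m, "abc"), 1.0)
        per, _ = topology.clustering_coefficient(tg)
        for v in "abc":
            assert per[v] == pytest.approx(0.5 ** (1.0 / 3.0), abs=1e-12)

    def test_regular_ring_has_no_hubs(self):
        m = np.zeros((6, 6))
        for i in range(6):
            m[i, (i + 1) % 6] = m[(i + 1) % 6, i] = 1.0
        tg = topology.proportional_threshold(cm_from(m, "abcdef"), 6 / 15)
        assert topology.identify_hubs(topology.betweenness(tg)).hubs == []


class TestAgainstOracles:
    def test_local_efficiency_matches_floyd_warshall(self, rng):
        for _ in range(5):
            m = random_weighted_matrix(rng, 7)
            tg = topology.proportional_threshold(
                cm_from(m, [f"n{i}" for i in range(7)]), 0.6)
            adj = nx.to_numpy_array(tg.graph, nodelist=tg.labels, weight="weight")
            per, _ = topology.local_efficiency(tg)
            np.testing.assert_allclose([per[l] for l in tg.labels],
                                       oracle_local_efficiency(adj), atol=1e-12)

    def test_clustering_matches_direct_summation(self, rng):
        for _ in range(5):
            m = random_weighted_matrix(rng, 7)
            tg = topology.proportional_threshold(
                cm_from(m, [f"n{i}" for i in range(7)]), 0.7)
            adj = nx.to_numpy_array(tg.graph, nodelist=tg.labels, weight="weight")
            per, _ = topology.clustering_coefficient(tg)
            np.testing.assert_allclose([per[l] for l in tg.labels],
                                       oracle_clustering(adj), atol=1e-12)

    def test_betweenness_matches_path_enumeration(self, rng):
        m = random_weighted_matrix(rng, 6)
        tg = topology.proportional_threshold(
            cm_from(m, [f"n{i}" for i in range(6)]), 0.6)
        adj = nx.to_numpy_array(tg.graph, nodelist=tg.labels, weight="weight")
        bc = topology.betweenness(tg)
        np.testing.assert_allclose([bc[l] for l in tg.labels],
                                   oracle_betweenness(adj), atol=1e-9)

    def test_label_permutation_equivariance(self, rng):
        m = random_weighted_matrix(rng, 8)
        labels = [f"n{i}" for i in range(8)]
        perm = list(rng.permutation(8))
        mp = m[np.ix_(perm, perm)]
        lp = [labels[i] for i in perm]
        tg1 = topology.proportional_threshold(cm_from(m, labels), 0.4)
        tg2 = topology.proportional_threshold(cm_from(mp, lp), 0.4)
        c1, _ = topology.clustering_coefficient(tg1)
        c2, _ = topology.clustering_coefficient(tg2)
        for l in labels:
            assert c1[l] == pytest.approx(c2[l], abs=1e-12)


class TestRichClub:
    def test_complete_graph_phi_one(self):
        m = np.ones((6, 6)) - np.eye(6)
        tg = topology.proportional_threshold(cm_from(m, "abcdef"), 1.0)
        curve = topology.rich_club(tg, n_nulls=10, seed=0)
        assert np.allclose(curve.phi[curve.defined], 1.0)

    def test_raw_phi_matches_networkx(self, rng):
        """Our raw coefficient against nx.rich_club_coefficient."""
        g = nx.gnm_random_graph(15, 40, seed=7)
        m = nx.to_numpy_array(g)
        tg = topology.proportional_threshold(
            cm_from(m, [f"n{i}" for i in range(15)]), 40 / 105)
        curve = topology.rich_club(tg, n_nulls=10, seed=0)
        expected = nx.rich_club_coefficient(g, normalized=False)
        for k, phi in expected.items():
            if k < len(curve.phi) and curve.defined[k]:
                assert curve.phi[k] == pytest.approx(phi, abs=1e-12)

    def test_random_graph_normalized_near_one(self):
        """Degree-preserving normalization of ER-style graphs ~ 1 at low k."""
        vals = []
        for seed in range(12):
            g = nx.gnm_random_graph(20, 60, seed=seed)
            m = nx.to_numpy_array(g) * np.random.default_rng(seed).uniform(
                0.5, 1.0, size=(20, 20))
            m = (m + m.T) / 2
            tg = topology.proportional_threshold(
                cm_from(m, [f"n{i}" for i in range(20)]), 60 / 190)
            curve = topology.rich_club(tg, n_nulls=20, seed=seed)
            low_k = curve.defined & (curve.k <= 4)
            if np.any(low_k):
                vals.append(np.nanmean(curve.phi_norm[low_k]))
        assert 0.9 < np.mean(vals) < 1.1


class TestHemisphere:
    def test_partition_of_scalp_channels(self, montage64):
        left = montage64.hemisphere_labels("left")
        right = montage64.hemisphere_labels("right")
        mid = montage64.hemisphere_labels("midline")
        scalp = set(montage64.scalp_labels)
        assert len(left) == len(right) == 26
        assert set(left) | set(right) | set(mid) == scalp
        assert not (set(left) & set(right))

    def test_subnetwork_excludes_midline(self, montage64, rng):
        scalp = montage64.scalp_labels
        cm = cm_from(random_weighted_matrix(rng, 60), scalp)
        left = topology.hemisphere_subnetwork(cm, montage64, "left")
        assert "Pz" not in left.channel_labels
        assert len(left.channel_labels) == 26

    def test_unknown_side_rejected(self, montage64, rng):
        cm = cm_from(random_weighted_matrix(rng, 60), montage64.scalp_labels)
        with pytest.raises(ValueError, match="side"):
            topology.hemisphere_subnetwork(cm, montage64, "dorsal")

    def test_planted_left_coupling_raises_left_mean(self, montage64, rng):
        scalp = montage64.scalp_labels
        left = montage64.hemisphere_labels("left")
        pairs = [(a, b) for i, a in enumerate(left[:10]) for b in left[i + 1:10]]
        m = synth.sample_wpli_matrices(rng, 1, scalp, planted_edges=pairs,
                                       delta=0.2)[0]
        cm = cm_from(m, scalp)
        l = topology.hemisphere_subnetwork(cm, montage64, "left")
        r = topology.hemisphere_subnetwork(cm, montage64, "right")
        iu = np.triu_indices(26, 1)
        assert l.values[iu].mean() > r.values[iu].mean()


class TestGroupComparison:
    def test_table_covers_all_ten_thresholds(self, rng):
        a = rng.normal(size=(5, 10))
        b = rng.normal(size=(5, 10))
        df = topology.compare_topology_groups({"clustering": a}, {"clustering": b})
        per_sparsity = df[df["sparsity"].notna()]
        assert len(per_sparsity) == 10
        assert len(df) == 11  # + area-under-curve row

    def test_identical_groups_null(self, rng):
        a = rng.normal(size=(4, 10))
        df = topology.compare_topology_groups({"clustering": a},
                                              {"clustering": a.copy()})
        np.testing.assert_allclose(df["t"], 0.0)
        np.testing.assert_allclose(df["p"], 1.0)

    def test_planted_dense_block_raises_clustering(self, rng):
        """Stronger within-module coupling in group A shows up as higher
        clustering and local efficiency at mid sparsities."""
        labels = [f"n{i}" for i in range(20)]
        block = [(a, b) for i, a in enumerate(labels[:8]) for b in labels[i + 1:8]]
        wins = 0
        reps = 4
        for rep in range(reps):
            r = np.random.default_rng(3000 + rep)
            A, B = synth.sample_study_wpli(r, 8, labels, planted=[(block, 0.3)])
            mid = {"clustering": [[], []], "local_efficiency": [[], []]}
            for gi, grp in enumerate((A, B)):
                for m in grp:
                    tg = topology.proportional_threshold(cm_from(m, labels), 0.2)
                    mid["clustering"][gi].append(
                        topology.clustering_coefficient(tg)[1])
                    mid["local_efficiency"][gi].append(
                        topology.local_efficiency(tg)[1])
            df = topology.compare_topology_groups(
                {k: np.array(v[0])[:, None] for k, v in mid.items()},
                {k: np.array(v[1])[:, None] for k, v in mid.items()},
                sparsities=[0.2])
            per = df[df["sparsity"].notna()]
            if np.all(per["t"] > 0) and np.all(per["p"] < 0.05):
                wins += 1
        assert wins >= 3


def test_subject_topology_table_shape(rng):
    labels = [f"n{i}" for i in range(12)]
    cm = cm_from(random_weighted_matrix(rng, 12), labels)
    df = topology.subject_topology(cm)
    assert len(df) == 10
    assert set(["sparsity", "clustering", "local_efficiency", "hubs"]) <= set(df.columns)
    assert df["clustering"].between(0, 1).all()
    assert df["local_efficiency"].between(0, 1).all()
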