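"""Graph construction, small-world metrics, communities and aggregation."""
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thermofmri.core import ConfigError, InputError
from thermofmri.netbuild import (
    AdjacencyMatrix,
    aggregate_functional_groups,
    blondel_communities,
    build_adjacency,
    characteristic_path_length,
    fisher_z,
    global_regression,
    k_standardize,
    kamada_kawai_coordinates,
    mean_adjacency,
    small_world,
)


# --------------------------------------------------------------------------
# Brute-force topology oracles
# --------------------------------------------------------------------------
def brute_clustering(G):
    """Exhaustive triangle count per node (networkx-free arithmetic)."""
    nodes = list(G.nodes)
    adj = {n: set(G.neighbors(n)) for n in nodes}
    total = 0.0
    for n in nodes:
        k = len(adj[n])
        if k < 2:
            continue
        links = sum(1 for a, b in itertools.combinations(adj[n], 2) if b in adj[a])
        total += 2.0 * links / (k * (k - 1))
    return total / len(nodes)


def brute_path_length(G):
    """Floyd-Warshall over connected ordered pairs."""
    nodes = list(G.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    INF = float("inf")
    d = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    for u, v in G.edges:
        d[idx[u]][idx[v]] = d[idx[v]][idx[u]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    vals = [d[i][j] for i in range(n) for j in range(n) if i != j and d[i][j] < INF]
    return sum(vals) / len(vals)


class TestGlobalRegression:
    def test_residuals_orthogonal_to_global_mean(self):
        rng = np.random.default_rng(0)
        traces = rng.normal(size=(6, 80))
        resid = global_regression(traces)
        g = traces.mean(axis=0)
        gc = g - g.mean()
        dots = resid @ gc
        assert np.max(np.abs(dots)) < 1e-8 * np.linalg.norm(gc) * np.linalg.norm(resid, axis=1).max()

    def test_trace_equal_to_global_mean_vanishes(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=80)
        traces = np.stack([base, base, base])
        resid = global_regression(traces)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_recovers_orthogonal_component(self):
        rng = np.random.default_rng(2)
        g = rng.normal(size=200)
        s = rng.normal(size=200)
        gc = g - g.mean()
        s -= s.mean()
        s -= (s @ gc) / (gc @ gc) * gc  # make s exactly orthogonal to g
        # paired construction keeps the global mean proportional to g
        traces = np.vstack([2.0 * g + s, 2.0 * g - s])
        resid = global_regression(traces)
        assert np.allclose(resid[0], s, atol=1e-6)

    def test_zero_variance_global_mean_warns(self):
        traces = np.stack([np.ones(10), -np.ones(10)])  # global mean constant 0
        with pytest.warns(UserWarning, match="zero-variance"):
            resid = global_regression(traces)
        # falls back to mean-centering each trace
        assert np.allclose(resid, 0.0)

    def test_needs_two_traces(self):
        with pytest.raises(InputError):
            global_regression(np.ones((1, 10)))


class TestBuildAdjacency:
    def test_fisher_z_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_identical_traces_clipped_finite(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=50)
        mat = build_adjacency(np.stack([t, t, rng.normal(size=50)]))
        assert np.isfinite(mat.values[0, 1])
        assert mat.values[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_white_noise_correlations_small(self):
        rng = np.random.default_rng(4)
        mat = build_adjacency(rng.normal(size=(10, 1500)))
        off = mat.values[~np.eye(10, dtype=bool)]
        assert np.abs(np.tanh(off)).max() < 0.1  # |r| < 0.1 at t = 1500

    def test_constant_trace_excluded_as_nan(self):
        rng = np.random.default_rng(5)
        traces = np.vstack([np.ones(50), rng.normal(size=(3, 50))])
        mat = build_adjacency(traces)
        assert np.isnan(mat.values[0, 1:]).all()
        assert np.isnan(mat.values[1:, 0]).all()
        assert np.isfinite(mat.values[1:, 1:]).all()

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(6)
        mat = build_adjacency(rng.normal(size=(7, 60)))
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 0.0)

    def test_mean_adjacency_elementwise(self):
        rng = np.random.default_rng(7)
        mats = [build_adjacency(rng.normal(size=(4, 40))) for _ in range(3)]
        mean = mean_adjacency(mats)
        assert np.allclose(mean.values, np.mean([m.values for m in mats], axis=0))


class TestKStandardize:
    @staticmethod
    def random_matrix(n, seed, directed=False):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(n, n))
        if not directed:
            vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        return AdjacencyMatrix(values=vals, nodes=list(range(1, n + 1)),
                               mode="directed" if directed else "symmetric")

    def test_202_nodes_k10_symmetric_1010_edges(self):
        net = k_standardize(self.random_matrix(202, 0), k=10)
        assert net.number_of_edges() == 1010

    def test_202_nodes_k10_directed_2020_edges(self):
        net = k_standardize(self.random_matrix(202, 1, directed=True), k=10)
        assert net.number_of_edges() == 2020

    def test_undersupply_keeps_all_with_warning(self):
        vals = np.zeros((202, 202))
        for i, j in [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)]:
            vals[i, j] = vals[j, i] = 0.5
        mat = AdjacencyMatrix(values=vals, nodes=list(range(202)))
        with pytest.warns(UserWarning, match="positive connections"):
            net = k_standardize(mat, k=10)
        assert net.number_of_edges() == 5

    def test_only_positive_weights_retained(self):
        net = k_standardize(self.random_matrix(30, 2), k=4)
        assert all(d["weight"] > 0 for _, _, d in net.edges(data=True))

    def test_deterministic_tie_breaking(self):
        vals = np.full((6, 6), 0.5)
        np.fill_diagonal(vals, 0.0)
        mat = AdjacencyMatrix(values=vals, nodes=list(range(6)))
        net = k_standardize(mat, k=2)  # m = 6 of 15 equal-weight candidates
        expected = [(0, 1), (0, 2), (0, 3), (0, 4), (0, 5), (1, 2)]
        assert sorted(net.edges()) == expected

    def test_invalid_k(self):
        with pytest.raises(ConfigError):
            k_standardize(self.random_matrix(6, 3), k=0)

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(8, 40), k=st.integers(1, 6), seed=st.integers(0, 1000))
    def test_edge_count_exact_whenever_supply_suffices(self, n, k, seed):
        mat = self.random_matrix(n, seed)
        m_target = n * k // 2
        n_pos = int((mat.values[np.triu_indices(n, 1)] > 0).sum())
        if n_pos < m_target:
            return
        assert k_standardize(mat, k=k).number_of_edges() == m_target


class TestSmallWorld:
    def test_random_graph_self_normalizes_to_one(self):
        # large enough that the clustering coefficient concentrates
        G = nx.gnm_random_graph(200, 2000, seed=1)
        sw = small_world(G, n_random=20, seed=0)
        assert sw.gamma == pytest.approx(1.0, abs=0.15)
        assert sw.lam == pytest.approx(1.0, abs=0.15)
        assert sw.sigma == pytest.approx(1.0, abs=0.15)
        assert sw.sigma == pytest.approx(sw.gamma / sw.lam)

    def test_ring_lattice_clustering_closed_form(self):
        k = 10
        G = nx.watts_strogatz_graph(100, k, 0.0, seed=0)  # ring lattice
        sw = small_world(G, n_random=5, seed=0)
        assert sw.c_raw == pytest.approx(3 * (k - 2) / (4 * (k - 1)), abs=1e-3)

    def test_path_graph_length_two(self):
        G = nx.path_graph(5)
        L, fragmented = characteristic_path_length(G)
        assert L == pytest.approx(2.0)
        assert L == pytest.approx(brute_path_length(G))
        assert not fragmented

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        G = nx.gnp_random_graph(n, 0.5, seed=seed + 100)
        if G.number_of_edges() == 0:
            return
        sw = small_world(G, n_random=3, seed=0)
        assert sw.c_raw == pytest.approx(brute_clustering(G), abs=1e-12)
        assert sw.l_raw == pytest.approx(brute_path_length(G), abs=1e-12)

    def test_adding_edge_never_increases_path_length(self):
        rng = np.random.default_rng(11)
        G = nx.gnm_random_graph(20, 30, seed=5)
        L0, _ = characteristic_path_length(G)
        comp = max(nx.connected_components(G), key=len)
        candidates = [
            (u, v) for u, v in itertools.combinations(sorted(comp), 2) if not G.has_edge(u, v)
        ]
        u, v = candidates[int(rng.integers(len(candidates)))]
        G.add_edge(u, v)
        L1, _ = characteristic_path_length(G)
        assert L1 <= L0 + 1e-12

    def test_reproducible_under_seed(self):
        G = nx.gnm_random_graph(40, 120, seed=2)
        a = small_world(G, n_random=20, seed=7)
        b = small_world(G, n_random=20, seed=7)
        assert (a.gamma, a.lam, a.sigma) == (b.gamma, b.lam, b.sigma)

    def test_empty_graph_rejected(self):
        with pytest.raises(InputError):
            small_world(nx.empty_graph(5))


class TestBlondelCommunities:
    def test_two_disjoint_cliques(self):
        G = nx.disjoint_union(nx.complete_graph(10), nx.complete_graph(10))
        part = blondel_communities(G, seed=0)
        assert part.n_communities == 2
        first = {n for n, c in part.membership.items() if c == part.membership[0]}
        assert first == set(range(10))
        assert part.modularity >= 0.0

    def test_planted_partition_recovery(self):
        """Four 15-node blocks (p_in 0.9, p_out 0.05) recovered with adjusted
        agreement >= 0.9 in at least 95 of 100 seeded runs."""
        from sklearn.metrics import adjusted_rand_score

        sizes = [15, 15, 15, 15]
        truth = np.repeat(np.arange(4), 15)
        good = 0
        for seed in range(100):
            G = nx.stochastic_block_model(sizes, np.full((4, 4), 0.05) + 0.85 * np.eye(4), seed=seed)
            part = blondel_communities(G, seed=seed)
            labels = [part.membership[i] for i in range(60)]
            if adjusted_rand_score(truth, labels) >= 0.9:
                good += 1
        assert good >= 95

    def test_seed_determinism(self):
        G = nx.gnm_random_graph(30, 90, seed=3)
        a = blondel_communities(G, seed=5)
        b = blondel_communities(G, seed=5)
        assert a.membership == b.membership

    def test_requires_an_edge(self):
        with pytest.raises(InputError):
            blondel_communities(nx.empty_graph(4))


class TestAggregateFunctionalGroups:
    @staticmethod
    def table(groups):
        return pd.DataFrame(
            {"label_id": list(groups), "functional_group": [groups[k] for k in groups]}
        )

    def test_singleton_groups_identity(self):
        G = nx.Graph()
        G.add_weighted_edges_from([(1, 2, 0.5), (2, 3, 0.7)])
        table = self.table({1: "a", 2: "b", 3: "c"})
        C = aggregate_functional_groups(G, table)
        assert C.number_of_nodes() == 3
        assert C["a"]["b"]["weight"] == pytest.approx(0.5)
        assert C["b"]["c"]["weight"] == pytest.approx(0.7)

    def test_total_weight_conserved(self):
        rng = np.random.default_rng(8)
        G = nx.gnm_random_graph(12, 30, seed=4)
        for u, v in G.edges:
            G[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
        groups = {n: f"g{n % 3}" for n in G.nodes}
        C = aggregate_functional_groups(G, self.table(groups))
        total = sum(d["weight"] for _, _, d in C.edges(data=True))
        total += sum(C.nodes[n]["within_weight"] for n in C.nodes)
        expected = sum(d["weight"] for _, _, d in G.edges(data=True))
        assert total == pytest.approx(expected)

    def test_condensed_degree_counts_member_edges(self):
        """Two structures in one group with 3 and 4 external edges give a
        condensed node of degree 7."""
        G = nx.Graph()
        G.add_edges_from([(1, 10), (1, 11), (1, 12), (2, 13), (2, 14), (2, 15), (2, 16)])
        groups = {1: "core", 2: "core"}
        groups.update({n: f"ext{n}" for n in range(10, 17)})
        C = aggregate_functional_groups(G, self.table(groups))
        assert C.nodes["core"]["degree"] == 7

    def test_respect_communities_splits_groups(self):
        G = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        groups = {n: "ctx" for n in G.nodes}
        part = blondel_communities(G, seed=0)
        C = aggregate_functional_groups(G, self.table(groups), respect_communities=True, partition=part)
        assert C.number_of_nodes() == 2  # one "ctx" node per community

    def test_unknown_group_raises(self):
        G = nx.Graph()
        G.add_edge(1, 99)
        with pytest.raises(InputError):
            aggregate_functional_groups(G, self.table({1: "a"}))

    def test_layout_export_shape(self):
        G = nx.gnm_random_graph(10, 20, seed=6)
        coords = kamada_kawai_coordinates(G)
        assert list(coords.columns) == ["node", "x", "y"]
        assert len(coords) == 10
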