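import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from phylotraits.exceptions import DesignError, ValidationError
from phylotraits.network import (
    build_network,
    global_metrics,
    node_metrics,
    pearson_with_p,
)
from phylotraits.simulate import simulate_correlated_means


def exact_corr_columns(n, r, seed=0):
    """Two columns whose sample correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ x) / (x @ x) * x  # orthogonalize
    z /= z.std()
    y = r * x + math.sqrt(1 - r * r) * z
    return x, y


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson_with_p(x, x)[0] == pytest.approx(1.0)
        assert pearson_with_p(x, -x)[0] == pytest.approx(-1.0)

    def test_zero_variance_error(self):
        with pytest.raises(ValidationError):
            pearson_with_p(np.ones(5), np.arange(5.0))

    def test_n_minimum(self):
        with pytest.raises(DesignError):
            pearson_with_p(np.arange(3.0), np.arange(3.0))

    def test_p_matches_quadrature_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = 0.6 * x + rng.normal(size=10)
        r, p = pearson_with_p(x, y)
        n = 10
        t_obs = abs(r) * math.sqrt((n - 2) / (1 - r * r))
        df = n - 2
        # t density integrated numerically over the two tails
        const = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        dens = lambda t: const * (1 + t * t / df) ** (-(df + 1) / 2)
        tail, _ = integrate.quad(dens, t_obs, np.inf)
        assert p == pytest.approx(2 * tail, abs=1e-8)


class TestBuildNetwork:
    def test_no_significant_pairs(self):
        # exactly orthogonal columns: all sample correlations are ~0, p ~ 1
        rng = np.random.default_rng(1)
        M = rng.normal(size=(20, 6))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        means = pd.DataFrame(Q, columns=list("abcdef"))
        net = build_network(means, site=1000)
        assert net.graph.number_of_nodes() == 6
        assert net.graph.number_of_edges() == 0
        assert global_metrics(net).edge_density == 0.0

    def test_weight_is_floor_of_ten_r(self):
        x, y = exact_corr_columns(40, 0.55, seed=2)
        means = pd.DataFrame({"a": x, "b": y})
        net = build_network(means)
        assert net.graph.edges[("a", "b")]["weight"] == 5

    def test_sign_recorded(self):
        x, y = exact_corr_columns(40, -0.8, seed=3)
        net = build_network(pd.DataFrame({"a": x, "b": y}))
        assert net.graph.edges[("a", "b")]["sign"] == -1
        el = net.edge_list()
        assert list(el.columns) == ["trait_a", "trait_b", "r", "p", "weight", "sign"]

    def test_isolated_nodes_retained(self):
        corr = np.eye(4)
        corr[0, 1] = corr[1, 0] = 0.95
        means = simulate_correlated_means(200, corr, seed=4, traits=list("abcd"))
        net = build_network(means, alpha=1e-6)
        assert set(net.graph.nodes) == set("abcd")
        assert net.graph.has_edge("a", "b")
        assert net.graph.degree("c") == 0

    def test_constant_trait_isolated_with_warning(self):
        rng = np.random.default_rng(6)
        means = pd.DataFrame({"a": rng.normal(size=10), "b": np.full(10, 3.0)})
        with pytest.warns(UserWarning, match="'b' is constant"):
            net = build_network(means)
        assert net.graph.degree("b") == 0

    def test_minimum_species(self):
        with pytest.raises(DesignError):
            build_network(pd.DataFrame({"a": [1, 2, 3], "b": [2, 1, 3]}))

    def test_edge_set_invariant_to_row_permutation(self):
        corr = np.eye(5)
        for i, j, r in [(0, 1, 0.8), (1, 2, 0.6), (3, 4, -0.7)]:
            corr[i, j] = corr[j, i] = r
        means = simulate_correlated_means(60, corr, seed=9, traits=list("abcde"))
        net1 = build_network(means)
        net2 = build_network(means.sample(frac=1, random_state=11))
        assert set(net1.graph.edges) == set(net2.graph.edges)


def brute_force_metrics(g: nx.Graph):
    """Independent BFS/enumeration implementation of all topology metrics."""
    nodes = list(g.nodes)
    n = len(nodes)
    # BFS distances
    dist = {}
    for s in nodes:
        d = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v not in d:
                        d[v] = d[u] + 1
                        nxt.append(v)
            frontier = nxt
        dist[s] = d
    finite = [dist[a][b] for a in nodes for b in nodes if a != b and b in dist[a]]
    apl = sum(finite) / len(finite) if finite else float("nan")
    density = g.number_of_edges() / (n * (n - 1) / 2)
    # local clustering via triangle counting, degree >= 2 only
    cls = []
    for v in nodes:
        nb = list(g.neighbors(v))
        if len(nb) < 2:
            continue
        links = sum(1 for a, b in itertools.combinations(nb, 2) if g.has_edge(a, b))
        cls.append(links / (len(nb) * (len(nb) - 1) / 2))
    acc = sum(cls) / len(cls) if cls else float("nan")
    # betweenness by shortest-path enumeration
    betw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        if t not in dist[s]:
            continue
        d_st = dist[s][t]
        paths = [[s]]
        complete = []
        while paths:
            path = paths.pop()
            u = path[-1]
            if u == t:
                complete.append(path)
                continue
            for v in g.neighbors(u):
                if v in dist[s] and dist[s][v] == len(path) and dist[t].get(v, 1e9) == d_st - len(path):
                    paths.append(path + [v])
        for path in complete:
            for v in path[1:-1]:
                betw[v] += 1.0 / len(complete)
    return density, apl, acc, betw


class TestMetrics:
    def test_star_graph(self):
        g = nx.star_graph(4)  # center 0, unit weights
        nx.set_edge_attributes(g, 1, "weight")
        nm = node_metrics(g).set_index("trait")
        assert nm.loc[0, "degree"] == 4
        assert nm.loc[0, "strength"] == 4
        assert nm.loc[0, "betweenness"] == 6.0

    def test_triangle_betweenness_zero(self):
        g = nx.complete_graph(3)
        assert (node_metrics(g)["betweenness"] == 0).all()

    def test_path_graph_globals(self):
        g = nx.path_graph(3)
        m = global_metrics(g)
        assert m.edge_density == pytest.approx(2 / 3)
        assert m.average_path_length == pytest.approx(4 / 3)
        assert m.average_clustering == 0.0

    def test_complete_graph_globals(self):
        m = global_metrics(nx.complete_graph(4))
        assert (m.edge_density, m.average_path_length, m.average_clustering) == (1, 1, 1)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 11))
            p = float(rng.uniform(0.15, 0.7))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            density, apl, acc, betw = brute_force_metrics(g)
            m = global_metrics(g)
            assert m.edge_density == pytest.approx(density, abs=1e-12)
            if math.isnan(apl):
                assert math.isnan(m.average_path_length)
            else:
                assert m.average_path_length == pytest.approx(apl, abs=1e-12)
            if math.isnan(acc):
                assert math.isnan(m.average_clustering)
            else:
                assert m.average_clustering == pytest.approx(acc, abs=1e-12)
            nm = node_metrics(g).set_index("trait")
            for v in g.nodes:
                assert nm.loc[v, "betweenness"] == pytest.approx(betw[v], abs=1e-9)

    def test_isolated_node_changes_density_only(self):
        g = nx.path_graph(4)
        m1 = global_metrics(g)
        g2 = g.copy()
        g2.add_node("iso")
        m2 = global_metrics(g2)
        assert m2.edge_density < m1.edge_density
        assert m2.average_path_length == m1.average_path_length
        assert m2.average_clustering == m1.average_clustering

    def test_adding_edge_never_increases_path_length(self):
        # monotonicity holds whenever the reachable pair set is unchanged,
        # i.e. on already-connected graphs
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(40):
            g = nx.gnp_random_graph(8, 0.45, seed=int(rng.integers(2**31)))
            non_edges = list(nx.non_edges(g))
            if not non_edges or not nx.is_connected(g):
                continue
            before = global_metrics(g).average_path_length
            g.add_edge(*non_edges[int(rng.integers(len(non_edges)))])
            after = global_metrics(g).average_path_length
            assert after <= before + 1e-12
            checked += 1
        assert checked >= 10
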