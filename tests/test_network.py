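import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from sclcnet import (
    EnrichmentMatrix,
    ExpressionMatrix,
    NetworkConfig,
    build_adjacency,
    filter_network,
    find_hubs,
    hub_cell_correlation,
    spanning_forest,
)


def graph(edges: dict[tuple[str, str], float], extra_nodes=()) -> nx.Graph:
    G = nx.Graph()
    for (u, v), w in edges.items():
        G.add_edge(u, v, weight=w)
    G.add_nodes_from(extra_nodes)
    return G


def exact_corr_matrix() -> ExpressionMatrix:
    """Three genes over 4 samples with corr(A,B) = 0.5 and corr(A,C) = -0.5."""
    u = np.array([1.0, 0.0, -1.0, 0.0])
    v = np.array([0.0, 1.0, 0.0, -1.0])
    return ExpressionMatrix(
        pd.DataFrame(
            {
                "A": u,
                "B": 0.5 * u + np.sqrt(0.75) * v,
                "C": -0.5 * u + np.sqrt(0.75) * v,
            },
            index=[f"s{i}" for i in range(4)],
        ).T
    )


class TestBuildAdjacency:
    def test_soft_threshold_power_of_half(self):
        G = build_adjacency(exact_corr_matrix(), ["A", "B", "C"],
                            NetworkConfig(beta=6))
        assert G["A"]["B"]["weight"] == pytest.approx(0.5**6)  # 0.015625

    def test_negative_correlation_same_unsigned_weight(self):
        G = build_adjacency(exact_corr_matrix(), ["A", "B", "C"],
                            NetworkConfig(beta=6))
        assert G["A"]["C"]["weight"] == pytest.approx(0.015625)

    def test_signed_adjacency_discounts_negative(self):
        G = build_adjacency(exact_corr_matrix(), ["A", "B", "C"],
                            NetworkConfig(beta=2, signed=True))
        assert G["A"]["B"]["weight"] == pytest.approx(0.75**2)
        assert G["A"]["C"]["weight"] == pytest.approx(0.25**2)

    def test_perfect_correlation_weight_one(self):
        X = ExpressionMatrix(
            pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [2.0, 4.0, 6.0]},
                         index=["s1", "s2", "s3"]).T
        )
        G = build_adjacency(X, ["A", "B"], NetworkConfig(beta=7))
        assert G["A"]["B"]["weight"] == pytest.approx(1.0)

    def test_zero_variance_gene_named(self):
        X = ExpressionMatrix(
            pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [5.0, 5.0, 5.0]},
                         index=["s1", "s2", "s3"]).T
        )
        with pytest.raises(ValueError, match="'B'"):
            build_adjacency(X, ["A", "B"])

    def test_panel_gene_absent_rejected(self):
        with pytest.raises(KeyError, match="Z"):
            build_adjacency(exact_corr_matrix(), ["A", "Z"])


class TestFilterNetwork:
    def test_weight_floor_is_strict(self):
        G = graph({("A", "B"): 0.01, ("A", "C"): 0.5})
        out = filter_network(G, NetworkConfig(min_weight=0.01, top_frac=1.0))
        assert not out.has_edge("A", "B")  # exactly at the floor: removed
        assert out.has_edge("A", "C")
        assert set(out.nodes) == {"A", "B", "C"}  # isolated node kept

    def test_complete_k4_equal_weights_becomes_lex_star(self):
        # each node marks ceil(0.3*3)=1 edge, ties to its lexicographically
        # smallest partner; the union is the star on A with 3 edges
        G = graph({(u, v): 0.5 for u, v in
                   itertools.combinations("ABCD", 2)})
        out = filter_network(G, NetworkConfig(top_frac=0.30))
        assert sorted(tuple(sorted(e)) for e in out.edges) == [
            ("A", "B"), ("A", "C"), ("A", "D")
        ]

    def test_noop_configuration(self):
        G = graph({("A", "B"): 0.2, ("B", "C"): 0.9, ("A", "C"): 0.4})
        out = filter_network(G, NetworkConfig(min_weight=0.0, top_frac=1.0))
        assert set(out.edges) == set(G.edges)

    def test_threshold_applies_before_top_fraction(self):
        # node A has 4 incident edges, one below the floor; counting it
        # before thresholding would let A mark 2 edges instead of 1
        edges = {("A", "B"): 0.5, ("A", "C"): 0.4, ("A", "D"): 0.3,
                 ("A", "E"): 0.005,
                 ("B", "F"): 0.9, ("C", "F"): 0.9, ("D", "F"): 0.9}
        G = graph(edges)
        out = filter_network(G, NetworkConfig(min_weight=0.01, top_frac=0.30))
        kept = {tuple(sorted(e)) for e in out.edges}
        assert kept == {("A", "B"), ("B", "F"), ("C", "F"), ("D", "F")}

        # reversed stage order keeps ("A","C") as well — the order matters
        import math

        marked = set()
        for node in G.nodes:
            inc = sorted(
                ((G[node][p]["weight"], p) for p in G[node]),
                key=lambda t: (-t[0], t[1]),
            )
            k = math.ceil(0.30 * len(inc))
            marked |= {tuple(sorted((node, p))) for _, p in inc[:k]}
        reversed_kept = {e for e in marked
                         if G[e[0]][e[1]]["weight"] > 0.01}
        assert ("A", "C") in reversed_kept and reversed_kept != kept

    def test_output_is_subset_of_input(self, rng):
        G = nx.gnp_random_graph(12, 0.6, seed=5)
        G = nx.relabel_nodes(G, {i: f"g{i:02d}" for i in G.nodes})
        for u, v in G.edges:
            G[u][v]["weight"] = float(rng.uniform(0, 1))
        out = filter_network(G, NetworkConfig())
        assert set(map(frozenset, out.edges)) <= set(map(frozenset, G.edges))
        assert set(out.nodes) == set(G.nodes)


def brute_force_msf_distance(G: nx.Graph) -> float:
    """Minimum spanning-tree distance by enumerating edge subsets."""
    nodes = list(G.nodes)
    edges = [(u, v, 1.0 - d["weight"]) for u, v, d in G.edges(data=True)]
    n = len(nodes)
    best = np.inf
    for subset in itertools.combinations(edges, n - 1):
        T = nx.Graph()
        T.add_nodes_from(nodes)
        T.add_edges_from((u, v) for u, v, _ in subset)
        if nx.is_connected(T):
            best = min(best, sum(d for _, _, d in subset))
    return best


class TestSpanningForest:
    def test_triangle_picks_two_cheapest_edges(self):
        # distances AB=0.1, BC=0.2, AC=0.3 -> tree {AB, BC}, total 0.3
        G = graph({("A", "B"): 0.9, ("B", "C"): 0.8, ("A", "C"): 0.7})
        F = spanning_forest(G)
        assert sorted(tuple(sorted(e)) for e in F.edges) == [("A", "B"), ("B", "C")]
        total = sum(1.0 - F[u][v]["weight"] for u, v in F.edges)
        assert total == pytest.approx(0.3)

    def test_connected_graph_gives_n_minus_1_edges(self, rng):
        G = nx.complete_graph(7)
        G = nx.relabel_nodes(G, {i: f"g{i}" for i in G.nodes})
        for u, v in G.edges:
            G[u][v]["weight"] = float(rng.uniform(0, 1))
        assert spanning_forest(G).number_of_edges() == 6

    def test_disconnected_input_keeps_components(self):
        G = graph({("A", "B"): 0.5, ("C", "D"): 0.5})
        F = spanning_forest(G)
        assert F.number_of_edges() == 2
        assert nx.number_connected_components(F) == 2

    def test_empty_graph_gives_empty_forest(self):
        F = spanning_forest(nx.Graph())
        assert F.number_of_nodes() == 0

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 8))
            G = nx.gnp_random_graph(n, 0.7, seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(G) or G.number_of_edges() > 14:
                continue
            G = nx.relabel_nodes(G, {i: f"g{i}" for i in G.nodes})
            for u, v in G.edges:
                G[u][v]["weight"] = float(rng.uniform(0, 1))
            F = spanning_forest(G)
            total = sum(1.0 - F[u][v]["weight"] for u, v in F.edges)
            assert total == pytest.approx(brute_force_msf_distance(G))

    def test_deterministic_under_ties(self):
        G = graph({(u, v): 0.5 for u, v in itertools.combinations("ABCDE", 2)})
        F1 = spanning_forest(G)
        F2 = spanning_forest(G)
        assert sorted(F1.edges) == sorted(F2.edges)
        # lexicographic tie-break: Kruskal takes pairs in lex order -> star on A
        assert sorted(tuple(sorted(e)) for e in F1.edges) == [
            ("A", "B"), ("A", "C"), ("A", "D"), ("A", "E")
        ]


class TestFindHubs:
    def test_star_center_is_hub(self):
        G = graph({("HUB", f"L{i}"): 0.9 for i in range(6)})
        F = spanning_forest(G)
        report = find_hubs(F)
        assert report.iloc[0]["gene_id"] == "HUB"
        assert bool(report.iloc[0]["is_hub"]) and report.iloc[0]["degree"] == 6
        assert not report.iloc[1:]["is_hub"].any()

    def test_degree_exactly_four_is_not_hub(self):
        G = graph({("HUB", f"L{i}"): 0.9 for i in range(4)})
        report = find_hubs(spanning_forest(G))
        assert report.iloc[0]["degree"] == 4
        assert not report["is_hub"].any()

    def test_path_graph_has_no_hubs(self):
        G = graph({(f"n{i}", f"n{i + 1}"): 0.5 for i in range(9)})
        assert not find_hubs(spanning_forest(G))["is_hub"].any()


class TestHubCellCorrelation:
    def _setup(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(6)]
        gv = rng.normal(size=6)
        X = ExpressionMatrix(
            pd.DataFrame({"H": gv, "flat": np.ones(6)}, index=samples).T
        )
        E = EnrichmentMatrix(
            pd.DataFrame({"self": gv, "noise": rng.normal(size=6)},
                         index=samples).T
        )
        return X, E

    def test_self_correlation_is_one_with_zero_p(self):
        X, E = self._setup()
        out = hub_cell_correlation(X, ["H"], E)
        rec = out[out["set_name"] == "self"].iloc[0]
        assert rec["r"] == 1.0 and rec["p_value"] == 0.0

    def test_hand_pearson_example(self):
        samples = ["s1", "s2", "s3", "s4"]
        X = ExpressionMatrix(
            pd.DataFrame({"H": [1.0, 2.0, 3.0, 4.0]}, index=samples).T
        )
        E = EnrichmentMatrix(
            pd.DataFrame({"ct": [1.0, 2.0, 3.0, 5.0]}, index=samples).T
        )
        rec = hub_cell_correlation(X, ["H"], E).iloc[0]
        assert rec["r"] == pytest.approx(0.98270763, abs=1e-6)

    def test_zero_correlation_gives_p_one(self):
        samples = [f"s{i}" for i in range(5)]
        X = ExpressionMatrix(
            pd.DataFrame({"H": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=samples).T
        )
        E = EnrichmentMatrix(
            pd.DataFrame({"ct": [1.0, -1.0, 0.0, -1.0, 1.0]}, index=samples).T
        )
        rec = hub_cell_correlation(X, ["H"], E).iloc[0]
        assert rec["r"] == pytest.approx(0.0)
        assert rec["p_value"] == pytest.approx(1.0)

    def test_constant_vector_flagged(self):
        X, E = self._setup()
        out = hub_cell_correlation(X, ["flat"], E)
        assert out["degenerate"].all()
        assert out["r"].isna().all()

    def test_too_few_shared_samples_rejected(self):
        X, E = self._setup()
        X2 = X.subset_samples(["s0", "s1"])
        with pytest.raises(ValueError, match="3 shared samples"):
            hub_cell_correlation(X2, ["H"], E)
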