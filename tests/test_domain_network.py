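"""Domain-sharing graph construction and hub scoring.

The betweenness implementation is checked against a naive all-pairs
shortest-path-counting oracle (plain BFS, no networkx).
"""

from collections import deque
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from bmzone.domain_network import (
    betweenness_scores,
    build_domain_graph,
    connectivity_scores,
    degree_scores,
    rank_hubs,
    shared_domain_profile,
)
from bmzone.domains import DomainAnnotation


def _all_shortest_paths(graph, s):
    """BFS predecessor DAG from s, then explicit path enumeration."""
    dist = {s: 0}
    preds = {s: []}
    q = deque([s])
    while q:
        u = q.popleft()
        for w in graph.neighbors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                preds[w] = []
                q.append(w)
            if dist[w] == dist[u] + 1:
                preds[w].append(u)

    def expand(t):
        if t == s:
            return [[s]]
        return [path + [t] for u in preds[t] for path in expand(u)]

    return {t: expand(t) for t in dist}


def naive_betweenness(graph: nx.Graph) -> dict:
    """Brute-force normalized betweenness by listing every shortest path."""
    bc = {v: 0.0 for v in graph}
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        n = len(nodes)
        if n < 3:
            continue
        raw = {v: 0.0 for v in nodes}
        for i, s in enumerate(nodes):
            paths_from_s = _all_shortest_paths(graph, s)
            for t in nodes[i + 1:]:
                paths = paths_from_s.get(t, [])
                if not paths:
                    continue
                for path in paths:
                    for v in path[1:-1]:
                        raw[v] += 1.0 / len(paths)
        for v in nodes:
            bc[v] = raw[v] * 2.0 / ((n - 1) * (n - 2))
    return bc


def graph_from_domains(node_domains: dict) -> nx.Graph:
    ann = [
        DomainAnnotation(g, d, 1) for g, ds in node_domains.items() for d in ds
    ]
    enriched = {d for ds in node_domains.values() for d in ds}
    return build_domain_graph(sorted(node_domains), ann, enriched)


class TestGraphConstruction:
    def test_edge_weight_counts_distinct_shared_domains(self):
        g = graph_from_domains({"A": {"D1", "D2"}, "B": {"D2", "D3"}})
        assert g["A"]["B"]["weight"] == 1
        assert g["A"]["B"]["shared"] == ["D2"]

    def test_no_shared_domains_no_edge(self):
        g = graph_from_domains({"A": {"D1"}, "B": {"D2"}})
        assert not g.has_edge("A", "B")
        assert set(g.nodes) == {"A", "B"}  # isolated nodes retained

    def test_equals_brute_force_pairwise_intersection(self):
        rng = np.random.default_rng(5)
        domains = [f"D{i}" for i in range(12)]
        node_domains = {
            f"P{i:02d}": set(
                rng.choice(domains, size=rng.integers(1, 5), replace=False)
            )
            for i in range(40)
        }
        g = graph_from_domains(node_domains)
        for u, v in combinations(sorted(node_domains), 2):
            shared = node_domains[u] & node_domains[v]
            if shared:
                assert g[u][v]["weight"] == len(shared)
                assert set(g[u][v]["shared"]) == shared
            else:
                assert not g.has_edge(u, v)

    def test_only_enriched_domains_pair(self):
        ann = [DomainAnnotation("A", "D1", 1), DomainAnnotation("B", "D1", 1)]
        g = build_domain_graph(["A", "B"], ann, enriched={"OTHER"})
        assert g.number_of_edges() == 0


class TestScores:
    def test_triangle_and_star_closed_forms(self):
        tri = graph_from_domains({"A": {"D"}, "B": {"D"}, "C": {"D"}})
        assert set(degree_scores(tri).values()) == {2}
        assert set(betweenness_scores(tri).values()) == {0.0}

        star = nx.star_graph(4)  # center 0, 4 leaves
        deg = degree_scores(star)
        assert deg[0] == 4 and all(deg[i] == 1 for i in range(1, 5))
        bc = betweenness_scores(star)
        assert bc[0] == pytest.approx(1.0)  # all 6 pairs mediated
        assert all(bc[i] == 0.0 for i in range(1, 5))

    def test_path_graph_midpoint(self):
        g = nx.path_graph(["a", "b", "c"])
        bc = betweenness_scores(g)
        assert bc == {"a": 0.0, "b": pytest.approx(1.0), "c": 0.0}

    def test_degree_equals_adjacency_row_sums(self):
        g = nx.erdos_renyi_graph(50, 0.1, seed=3)
        rows = np.asarray(nx.to_numpy_array(g)).sum(axis=1)
        deg = degree_scores(g)
        assert all(deg[i] == rows[i] for i in g.nodes)

    @pytest.mark.parametrize("seed", range(10))
    def test_betweenness_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.05, 0.4)), seed=seed)
        got = betweenness_scores(g)
        want = naive_betweenness(g)
        for v in g.nodes:
            assert got[v] == pytest.approx(want[v], abs=1e-12)

    def test_tree_raw_betweenness_identity(self):
        # on a tree, summed raw BC equals sum over ordered pairs of
        # (path length - 1): every interior hop is mediated exactly once
        for seed in range(5):
            t = nx.random_labeled_tree(12, seed=seed)
            n = t.number_of_nodes()
            bc = betweenness_scores(t)
            raw_total = sum(bc.values()) * ((n - 1) * (n - 2)) / 2.0
            lengths = dict(nx.all_pairs_shortest_path_length(t))
            hops = sum(
                lengths[u][v] - 1 for u in t for v in t if u != v
            ) / 2.0
            assert raw_total == pytest.approx(hops)

    def test_small_components_score_zero(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("C")
        bc = betweenness_scores(g)
        assert bc == {"A": 0.0, "B": 0.0, "C": 0.0}

    def test_relabeling_permutes_scores(self):
        g = nx.gnp_random_graph(20, 0.2, seed=9)
        mapping = {i: f"N{i:02d}" for i in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        bc_g = betweenness_scores(g)
        bc_h = betweenness_scores(h)
        assert all(
            bc_h[mapping[i]] == pytest.approx(bc_g[i]) for i in g.nodes
        )


class TestRankingAndProfile:
    def test_star_center_tops_both_rankings(self):
        g = graph_from_domains(
            {"HUB": {"D"}, "L1": {"D"}, "L2": {"D", "E"}, "L3": {"E"}}
        )
        scores = connectivity_scores(g)
        top_deg, top_bc = rank_hubs(scores, k=1)
        assert top_deg == ["L2"] and top_bc == ["L2"]

    def test_k_larger_than_n_warns_and_returns_full(self):
        g = graph_from_domains({"A": {"D"}, "B": {"D"}})
        with pytest.warns(UserWarning):
            top_deg, _ = rank_hubs(connectivity_scores(g), k=10)
        assert top_deg == ["A", "B"]

    def test_profile_partner_total_equals_degree(self):
        rng = np.random.default_rng(2)
        domains = [f"D{i}" for i in range(8)]
        node_domains = {
            f"P{i:02d}": set(
                rng.choice(domains, size=rng.integers(1, 4), replace=False)
            )
            for i in range(25)
        }
        g = graph_from_domains(node_domains)
        deg = degree_scores(g)
        for node in g.nodes:
            profile, partners = shared_domain_profile(g, node)
            assert partners == deg[node]
            for d, count in profile.items():
                assert count == sum(
                    1
                    for other in g.nodes
                    if other != node and d in node_domains[other]
                )

    def test_isolated_node_profile_empty(self):
        g = graph_from_domains({"A": {"D1"}, "B": {"D2"}})
        profile, partners = shared_domain_profile(g, "A")
        assert profile == {} and partners == 0

    def test_unknown_node_raises(self):
        g = graph_from_domains({"A": {"D1"}})
        with pytest.raises(KeyError):
            shared_domain_profile(g, "GHOST")
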