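"""Domain-sharing network over the verified BM-zone registry.

Two proteins are linked when they share at least one BM-enriched domain;
the edge weight is the number of distinct shared accessions.  Degree and
betweenness centrality over this graph nominate hub proteins: a high degree
marks a protein sharing domains with many others (perlecan-like), while a
high betweenness marks a hybrid-domain protein bridging otherwise separate
modules (papilin-like).

Shortest paths are unweighted by default — edge weights count shared
domains, they are not distances.  A weighted mode (distance = 1/weight) is
available but off by default.  Betweenness is normalized by
2/((n-1)(n-2)) within each connected component of size n >= 3; smaller
components score 0, so scores are comparable across disconnected graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .domains import DomainAnnotation
from .registry import VerifiedRegistry

__all__ = [
    "build_domain_graph",
    "degree_scores",
    "betweenness_scores",
    "connectivity_scores",
    "rank_hubs",
    "shared_domain_profile",
    "write_edge_list",
    "write_sif",
    "write_scores",
]


def build_domain_graph(
    registry: VerifiedRegistry | Sequence[str],
    annotations: Iterable[DomainAnnotation],
    enriched: set[str],
) -> nx.Graph:
    """Build the shared-domain graph over registry genes.

    Only enriched accessions participate in pairing.  Every registry gene
    is a node even when isolated; each edge carries ``weight`` (number of
    distinct shared enriched domains) and ``shared`` (the sorted accession
    list).
    """
    if not enriched:
        raise ValueError("enriched domain set must be nonempty")
    symbols = (
        registry.symbols() if isinstance(registry, VerifiedRegistry) else list(registry)
    )
    node_domains: dict[str, set[str]] = {s: set() for s in symbols}
    for a in annotations:
        if a.protein in node_domains and a.domain in enriched:
            node_domains[a.protein].add(a.domain)
    bare = sorted(s for s, ds in node_domains.items() if not ds)
    if bare:
        warnings.warn(
            f"{len(bare)} registry gene(s) carry no enriched domains "
            "and will be isolated nodes",
            stacklevel=2,
        )

    g = nx.Graph()
    g.add_nodes_from(symbols)
    # invert to domain -> carriers; pair within each carrier list
    carriers: dict[str, list[str]] = {}
    for s, ds in node_domains.items():
        for d in ds:
            carriers.setdefault(d, []).append(s)
    shared: dict[tuple[str, str], set[str]] = {}
    for d, genes in carriers.items():
        for u, v in combinations(sorted(genes), 2):
            shared.setdefault((u, v), set()).add(d)
    for (u, v), ds in shared.items():
        g.add_edge(u, v, weight=len(ds), shared=sorted(ds))
    for s, ds in node_domains.items():
        g.nodes[s]["domains"] = sorted(ds)
    return g


def degree_scores(graph: nx.Graph) -> dict[str, int]:
    """Unweighted degree per node."""
    return {n: int(d) for n, d in graph.degree()}


def betweenness_scores(graph: nx.Graph, weighted: bool = False) -> dict[str, float]:
    """Betweenness centrality, normalized per connected component.

    BC(v) = sum over s != v != t of sigma_st(v)/sigma_st, scaled by
    2/((n-1)(n-2)) where n is the size of v's component; components with
    fewer than 3 nodes score 0.  With ``weighted=True`` shortest paths use
    distance = 1/weight.
    """
    scores: dict[str, float] = {n: 0.0 for n in graph.nodes}
    for comp in nx.connected_components(graph):
        if len(comp) < 3:
            continue
        sub = graph.subgraph(comp).copy()
        if weighted:
            for u, v, data in sub.edges(data=True):
                data["distance"] = 1.0 / data.get("weight", 1)
            bc = nx.betweenness_centrality(sub, normalized=True, weight="distance")
        else:
            bc = nx.betweenness_centrality(sub, normalized=True)
        scores.update({n: float(b) for n, b in bc.items()})
    return scores


def connectivity_scores(graph: nx.Graph, weighted: bool = False) -> pd.DataFrame:
    """Degree and betweenness per node as a symbol-sorted table."""
    deg = degree_scores(graph)
    bc = betweenness_scores(graph, weighted=weighted)
    df = pd.DataFrame(
        {
            "symbol": sorted(graph.nodes),
        }
    )
    df["degree"] = [deg[s] for s in df["symbol"]]
    df["betweenness"] = [bc[s] for s in df["symbol"]]
    return df


def rank_hubs(
    scores: pd.DataFrame, k: int = 10
) -> tuple[list[str], list[str]]:
    """Top-k nodes by degree and by betweenness (ties broken by symbol)."""
    n = len(scores)
    if k > n:
        warnings.warn(f"k={k} exceeds {n} nodes; returning full ranking",
                      stacklevel=2)
        k = n
    by_degree = scores.sort_values(
        ["degree", "symbol"], ascending=[False, True]
    )["symbol"].tolist()[:k]
    by_betweenness = scores.sort_values(
        ["betweenness", "symbol"], ascending=[False, True]
    )["symbol"].tolist()[:k]
    return by_degree, by_betweenness


def shared_domain_profile(graph: nx.Graph, node: str) -> tuple[dict[str, int], int]:
    """For each domain of ``node``, how many other nodes carry it.

    Returns (domain -> partner count, total distinct partners).  The total
    equals the node's degree in the graph.
    """
    if node not in graph:
        raise KeyError(f"unknown node: {node}")
    profile: dict[str, int] = {}
    partners: set[str] = set()
    node_domains = set(graph.nodes[node].get("domains", ()))
    for d in sorted(node_domains):
        carriers = [
            other
            for other in graph.nodes
            if other != node and d in set(graph.nodes[other].get("domains", ()))
        ]
        if carriers:
            profile[d] = len(carriers)
            partners.update(carriers)
    return profile, len(partners)


# ---------------------------------------------------------------------------
# Exports (Cytoscape-friendly)
# ---------------------------------------------------------------------------

def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    rows = [
        {
            "protein_a": u,
            "protein_b": v,
            "shared_domain_count": data["weight"],
            "shared_domains": ",".join(data["shared"]),
        }
        for u, v, data in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_sif(graph: nx.Graph, path: str | Path) -> None:
    lines = [f"{u}\tshares_domains\t{v}" for u, v in sorted(graph.edges)]
    isolated = sorted(n for n in graph.nodes if graph.degree(n) == 0)
    lines += isolated
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index=False, encoding="utf-8")
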