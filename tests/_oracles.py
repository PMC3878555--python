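"""Brute-force reference implementations used only by the tests.

These enumerate every simple path with networkx and apply the canonical
tie-break (minimum weight, then fewest edges, then lexicographically
smallest node sequence with the pair oriented source < target) by exhaustive
comparison.  They are deliberately independent of the package's Dijkstra
machinery so the two routes can disagree.
"""

from __future__ import annotations

import itertools

import networkx as nx

from spgenes import InteractionRecord, WeightedNetwork, build_network


def net_from_edges(edges: dict[tuple[str, str], int]) -> WeightedNetwork:
    """Build a network from a {(u, v): score} dict."""
    return build_network([InteractionRecord(a, b, s) for (a, b), s in edges.items()])


def to_nx(edges: dict[tuple[str, str], int]) -> nx.Graph:
    G = nx.Graph()
    for (a, b), s in edges.items():
        G.add_edge(a, b, weight=1000 - s)
    return G


def oracle_canonical_path(G: nx.Graph, a: str, b: str):
    """Exhaustive canonical path: (nodes, total_weight), or None."""
    src, dst = sorted((a, b))
    best = None
    for path in nx.all_simple_paths(G, src, dst):
        w = sum(G[u][v]["weight"] for u, v in zip(path, path[1:]))
        key = (w, len(path) - 1, tuple(path))
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[2], best[0]


def oracle_betweenness(G: nx.Graph, seeds) -> dict[str, int]:
    """Restricted betweenness by exhaustive enumeration of every pair path."""
    counts = {n: 0 for n in G}
    for a, b in itertools.combinations(sorted(seeds), 2):
        found = oracle_canonical_path(G, a, b) if nx.has_path(G, a, b) else None
        if found is None:
            continue
        for v in found[0][1:-1]:
            counts[v] += 1
    return counts


def random_scored_edges(rng) -> dict[tuple[str, str], int]:
    """A random scored graph on 4-10 nodes with random edge density."""
    n = int(rng.integers(4, 11))
    p = float(rng.uniform(0.2, 0.6))
    names = [f"N{i:02d}" for i in range(n)]
    edges: dict[tuple[str, str], int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(names[i], names[j])] = int(rng.integers(1, 1001))
    return edges
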