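"""Canonical seed-pair shortest paths and restricted betweenness.

One minimum-weight path is kept per unordered seed pair.  When several paths
tie on total weight, the path with fewest edges wins; among remaining ties,
the lexicographically smallest node sequence, with the pair oriented so the
source is the lexicographically smaller endpoint.  This canonical rule makes
every downstream quantity — betweenness counts, permutation fractions, output
files — reproducible bit for bit.

Distances come from :func:`scipy.sparse.csgraph.dijkstra` on hop-augmented
weights (see :meth:`WeightedNetwork.augmented`), which settles the first two
tie-break stages; the lexicographic stage is resolved by a greedy forward
walk on the shortest-path DAG: from the current node, step to the smallest
neighbour that still lies on an optimal source-target path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .network import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSet",
    "PathRecord",
    "BetweennessTable",
    "SeedMappingError",
    "map_seeds",
    "canonical_shortest_path",
    "seed_pair_paths",
    "restricted_betweenness",
    "shortest_path_genes",
]


class SeedMappingError(ValueError):
    """Seed identifiers could not be mapped onto enough network nodes."""


@dataclass(frozen=True)
class SeedSet:
    """Seed (known disease) genes partitioned by network membership.

    ``mapped`` is sorted lexicographically and duplicate-free; every entry is
    a network node.  ``unmapped`` preserves input order.
    """

    mapped: tuple[str, ...]
    unmapped: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.mapped)


@dataclass(frozen=True)
class PathRecord:
    """One canonical minimum-weight path between a seed pair.

    ``source`` is always the lexicographically smaller endpoint.
    """

    source: str
    target: str
    nodes: tuple[str, ...]
    total_weight: int

    @property
    def inner_nodes(self) -> tuple[str, ...]:
        return self.nodes[1:-1]


@dataclass(frozen=True)
class BetweennessTable:
    """Restricted betweenness: per node, the number of seed-pair canonical
    shortest paths on which it lies strictly between the endpoints."""

    counts: dict[str, int]

    def __getitem__(self, node: str) -> int:
        return self.counts[node]

    def nonzero(self) -> dict[str, int]:
        return {n: c for n, c in self.counts.items() if c > 0}

    def total(self) -> int:
        return sum(self.counts.values())


def map_seeds(network: WeightedNetwork, identifiers: Sequence[str]) -> SeedSet:
    """Partition seed identifiers into mapped / unmapped against the network.

    Duplicates collapse with a warning; fewer than two mapped seeds is fatal
    because no seed pair exists to connect.
    """
    if not identifiers:
        raise SeedMappingError("no seed identifiers supplied")
    seen: set[str] = set()
    mapped: list[str] = []
    unmapped: list[str] = []
    n_dupes = 0
    for ident in identifiers:
        if ident in seen:
            n_dupes += 1
            continue
        seen.add(ident)
        (mapped if network.has_node(ident) else unmapped).append(ident)
    if n_dupes:
        logger.warning("collapsed %d duplicate seed identifier(s)", n_dupes)
    for ident in unmapped:
        logger.info("seed %s not present in the network", ident)
    if not mapped:
        raise SeedMappingError(
            f"none of the {len(seen)} seed identifier(s) map to network nodes"
        )
    if len(mapped) == 1:
        raise SeedMappingError(
            f"only one seed ({mapped[0]}) maps to the network; no pairs to connect"
        )
    return SeedSet(mapped=tuple(sorted(mapped)), unmapped=tuple(unmapped))


# -- canonical path machinery ------------------------------------------------


def _walk(
    indptr: np.ndarray,
    indices: np.ndarray,
    data: np.ndarray,
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    a: int,
    b: int,
) -> list[int] | None:
    """Greedy lexicographic walk on the a->b shortest-path DAG.

    ``dist_a``/``dist_b`` are augmented distances from each endpoint.  A
    neighbour v of u is a valid next step iff it advances the distance from a
    by exactly the edge weight and stays on an optimal a-b path; among valid
    steps the smallest node index (= lexicographically smallest identifier)
    is taken.  All quantities are integers stored in float64, so equality
    comparisons are exact.
    """
    total = dist_a[b]
    if not np.isfinite(total):
        return None
    path = [a]
    u = a
    for _ in range(len(dist_a)):  # a simple path has < n steps
        if u == b:
            return path
        lo, hi = indptr[u], indptr[u + 1]
        nbrs = indices[lo:hi]
        w = data[lo:hi]
        ok = (dist_a[u] + w == dist_a[nbrs]) & (dist_a[nbrs] + dist_b[nbrs] == total)
        if not ok.any():  # pragma: no cover - impossible on a valid DAG
            raise RuntimeError("shortest-path DAG walk found no forward step")
        u = int(nbrs[ok].min())
        path.append(u)
    raise RuntimeError("shortest-path walk exceeded node count")  # pragma: no cover


def _pair_path_indices(
    csr: csr_matrix, dist: np.ndarray, seed_idx: np.ndarray
) -> Iterator[tuple[int, int, list[int] | None]]:
    """Canonical paths for every unordered pair of ``seed_idx``.

    ``dist`` holds one row of augmented distances per seed (same order as
    ``seed_idx``, which must be ascending).  Yields ``(i, j, node_indices)``
    with ``node_indices`` None for disconnected pairs.
    """
    indptr, indices, data = csr.indptr, csr.indices, csr.data
    k = len(seed_idx)
    for i in range(k):
        for j in range(i + 1, k):
            yield i, j, _walk(
                indptr, indices, data, dist[i], dist[j], int(seed_idx[i]), int(seed_idx[j])
            )


def _path_record(
    network: WeightedNetwork, path_idx: list[int], K: int, aug_total: float
) -> PathRecord:
    names = tuple(network.nodes[i] for i in path_idx)
    hops = len(names) - 1
    total_weight = int(round((aug_total - hops) / K))
    return PathRecord(
        source=names[0], target=names[-1], nodes=names, total_weight=total_weight
    )


def canonical_shortest_path(
    network: WeightedNetwork, source: str, target: str
) -> PathRecord | None:
    """The canonical minimum-weight path between two nodes, or None.

    The pair is oriented so the returned record's source is the smaller
    identifier, making the result identical for both call orders.  Returns
    ``None`` when the endpoints lie in different components.
    """
    if source == target:
        raise ValueError(f"source and target must differ, both are {source!r}")
    ia, ib = network.index(source), network.index(target)
    if ia > ib:
        ia, ib = ib, ia
    csr, K = network.augmented()
    dist = dijkstra(csr, directed=True, indices=[ia, ib])
    path_idx = _walk(csr.indptr, csr.indices, csr.data, dist[0], dist[1], ia, ib)
    if path_idx is None:
        return None
    return _path_record(network, path_idx, K, dist[0][ib])


def seed_pair_paths(network: WeightedNetwork, seeds: SeedSet) -> list[PathRecord]:
    """One canonical path per unordered mapped-seed pair, in sorted pair order.

    Pairs whose endpoints are in different components are skipped (counted in
    the log) and contribute nothing downstream.
    """
    if len(seeds.mapped) < 2:
        raise SeedMappingError("need at least two mapped seeds")
    seed_idx = np.array([network.index(s) for s in seeds.mapped], dtype=np.int64)
    csr, K = network.augmented()
    dist = dijkstra(csr, directed=True, indices=seed_idx)
    paths: list[PathRecord] = []
    n_skipped = 0
    for i, j, path_idx in _pair_path_indices(csr, dist, seed_idx):
        if path_idx is None:
            n_skipped += 1
            continue
        paths.append(_path_record(network, path_idx, K, dist[i][seed_idx[j]]))
    if n_skipped:
        logger.info("skipped %d disconnected seed pair(s)", n_skipped)
    return paths


def restricted_betweenness(
    paths: Iterable[PathRecord], network: WeightedNetwork
) -> BetweennessTable:
    """Count, for every network node, the seed-pair paths crossing it.

    A node is credited once per path in which it appears strictly between
    the endpoints; endpoints themselves earn nothing from their own pair but
    may be inner nodes of other pairs' paths.  Every network node gets a row,
    zeros included.
    """
    counts = dict.fromkeys(network.nodes, 0)
    for path in paths:
        if path.source == path.target:
            raise ValueError(f"degenerate path with equal endpoints: {path.source!r}")
        for node in path.nodes[1:-1]:
            counts[node] += 1
    return BetweennessTable(counts)


def shortest_path_genes(table: BetweennessTable) -> list[str]:
    """Nodes with betweenness > 0, sorted by descending count then name."""
    hits = table.nonzero()
    return sorted(hits, key=lambda n: (-hits[n], n))
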