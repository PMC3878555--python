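"""Scored interaction edge lists and the confidence-weighted undirected graph.

The input dialect is the STRING ``protein.links`` flavour: whitespace- or
tab-delimited lines ``protein1 protein2 combined_score`` with an optional
single header line, plain text or gzip.  An edge exists whenever the combined
score is greater than zero, and each retained edge carries the derived weight

    w(u, v) = 1000 - score(u, v)

so that high-confidence interactions are short.  Scores live on STRING's
integer 0-1000 scale; a weight of 0 (score 1000) is legal because Dijkstra
only needs non-negative weights.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, NamedTuple, Sequence, Union

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

MAX_SCORE = 1000

__all__ = [
    "MAX_SCORE",
    "InteractionRecord",
    "ParseStats",
    "WeightedNetwork",
    "EdgeListParseError",
    "ScoreDomainError",
    "parse_edge_list",
    "score_to_weight",
    "build_network",
    "write_edge_list",
]


class EdgeListParseError(ValueError):
    """A line of the edge list could not be interpreted."""


class ScoreDomainError(ValueError):
    """An interaction score fell outside the integer interval (0, 1000]."""


class InteractionRecord(NamedTuple):
    """One scored undirected interaction, as read from the edge list."""

    protein_a: str
    protein_b: str
    score: int


@dataclass
class ParseStats:
    """Bookkeeping emitted by :func:`parse_edge_list`."""

    n_lines: int = 0
    n_records: int = 0
    n_self_loops: int = 0
    n_nonpositive: int = 0
    header_skipped: bool = False


def score_to_weight(score: int) -> int:
    """Map a confidence score to an edge weight, ``weight = 1000 - score``.

    Raises :class:`ScoreDomainError` unless ``0 < score <= 1000``.
    """
    if not isinstance(score, (int, np.integer)) or isinstance(score, bool):
        raise ScoreDomainError(f"score must be an integer, got {score!r}")
    if not 0 < score <= MAX_SCORE:
        raise ScoreDomainError(
            f"score {score} outside the valid interval (0, {MAX_SCORE}]"
        )
    return MAX_SCORE - int(score)


Source = Union[str, os.PathLike, IO[str], Iterable[str]]


def _open_text(source: Source):
    """Return ``(line_iterable, needs_close)`` for a path or stream."""
    if isinstance(source, (str, os.PathLike)):
        path = os.fspath(source)
        if path.endswith(".gz"):
            return gzip.open(path, "rt"), True
        return open(path, "rt"), True
    return source, False


def parse_edge_list(
    source: Source,
    has_header: bool | None = None,
    stats: ParseStats | None = None,
) -> list[InteractionRecord]:
    """Parse a STRING-dialect edge list into interaction records.

    Parameters
    ----------
    source
        Path (plain or ``.gz``) or an iterable of text lines.
    has_header
        ``True``/``False`` to force, ``None`` to auto-detect (the first line
        is a header when its third field does not parse as an integer).
    stats
        Optional mutable :class:`ParseStats` populated in place; dropped
        self-interactions and non-positive scores are also logged.

    Self-pairs and records with score <= 0 are dropped, not errors; a
    malformed line (fewer than three fields, non-integer score) raises
    :class:`EdgeListParseError` naming the line number.
    """
    if stats is None:
        stats = ParseStats()
    stream, needs_close = _open_text(source)
    records: list[InteractionRecord] = []
    try:
        first_data_line = True
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line:
                continue
            stats.n_lines += 1
            fields = line.split()
            if first_data_line:
                first_data_line = False
                looks_like_header = len(fields) < 3 or not _is_int(fields[2])
                if has_header is True or (has_header is None and looks_like_header):
                    stats.header_skipped = True
                    continue
            if len(fields) < 3:
                raise EdgeListParseError(
                    f"line {lineno}: expected >= 3 whitespace-separated fields, "
                    f"got {len(fields)}"
                )
            if not _is_int(fields[2]):
                raise EdgeListParseError(
                    f"line {lineno}: third field {fields[2]!r} is not an integer score"
                )
            a, b, score = fields[0], fields[1], int(fields[2])
            if a == b:
                stats.n_self_loops += 1
                continue
            if score <= 0:
                stats.n_nonpositive += 1
                continue
            records.append(InteractionRecord(a, b, score))
            stats.n_records += 1
    finally:
        if needs_close:
            stream.close()
    if stats.n_self_loops:
        logger.info("dropped %d self-interaction record(s)", stats.n_self_loops)
    if stats.n_nonpositive:
        logger.info("dropped %d record(s) with score <= 0", stats.n_nonpositive)
    return records


def _is_int(token: str) -> bool:
    try:
        int(token)
    except ValueError:
        return False
    return True


class WeightedNetwork:
    """Undirected protein network with integer confidence scores.

    Nodes are opaque string identifiers held in lexicographic order, so node
    index order coincides with identifier order; edges are stored once per
    unordered pair.  The network is immutable after construction.
    """

    def __init__(self, scores: dict[tuple[str, str], int]):
        for (a, b), s in scores.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a > b:
                raise ValueError(f"edge key ({a!r}, {b!r}) not canonically ordered")
            score_to_weight(s)  # validates the domain
        names: set[str] = set()
        for a, b in scores:
            names.add(a)
            names.add(b)
        self._nodes: tuple[str, ...] = tuple(sorted(names))
        self._index: dict[str, int] = {n: i for i, n in enumerate(self._nodes)}
        self._scores: dict[tuple[str, str], int] = dict(scores)
        self._adj: dict[str, dict[str, int]] = {n: {} for n in self._nodes}
        for (a, b), s in scores.items():
            self._adj[a][b] = s
            self._adj[b][a] = s
        self._aug: tuple[sparse.csr_matrix, int] | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._scores)

    def has_node(self, node: str) -> bool:
        return node in self._index

    __contains__ = has_node

    def index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def neighbors(self, node: str) -> tuple[str, ...]:
        self.index(node)
        return tuple(sorted(self._adj[node]))

    def degree(self, node: str) -> int:
        self.index(node)
        return len(self._adj[node])

    def edges(self) -> Iterator[tuple[str, str, int, int]]:
        """Yield ``(u, v, score, weight)`` in sorted pair order, u < v."""
        for (a, b) in sorted(self._scores):
            s = self._scores[(a, b)]
            yield a, b, s, MAX_SCORE - s

    def score(self, u: str, v: str) -> int:
        a, b = (u, v) if u < v else (v, u)
        try:
            return self._scores[(a, b)]
        except KeyError:
            raise KeyError(f"no edge between {u!r} and {v!r}") from None

    def weight(self, u: str, v: str) -> int:
        return MAX_SCORE - self.score(u, v)

    # -- distance machinery -------------------------------------------------

    def augmented(self) -> tuple[sparse.csr_matrix, int]:
        """Symmetric CSR of hop-augmented weights, plus the hop factor ``K``.

        Each edge carries ``w * K + 1`` with ``K = n_nodes``, which exceeds
        the largest possible hop count.  Minimising the augmented distance
        therefore minimises total weight first and, among weight ties, the
        number of edges — the first two stages of the canonical tie-break —
        while keeping every entry a positive integer (exact in float64 at
        these magnitudes).
        """
        if self._aug is None:
            n = self.n_nodes
            K = max(n, 2)
            m = self.n_edges
            rows = np.empty(2 * m, dtype=np.int64)
            cols = np.empty(2 * m, dtype=np.int64)
            data = np.empty(2 * m, dtype=np.float64)
            for k, ((a, b), s) in enumerate(self._scores.items()):
                ia, ib = self._index[a], self._index[b]
                aug = (MAX_SCORE - s) * K + 1
                rows[2 * k], cols[2 * k], data[2 * k] = ia, ib, aug
                rows[2 * k + 1], cols[2 * k + 1], data[2 * k + 1] = ib, ia, aug
            mat = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
            mat.sort_indices()
            self._aug = (mat, K)
        return self._aug

    def __repr__(self) -> str:  # pragma: no cover
        return f"WeightedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def build_network(
    records: Sequence[InteractionRecord], min_score: int = 1
) -> WeightedNetwork:
    """Assemble the undirected weighted network from parsed records.

    Duplicate records for the same unordered pair (including the symmetric
    duplicates STRING files normally contain) collapse to one edge keeping
    the maximum score.  Records below ``min_score`` are discarded; the
    default of 1 reproduces the score-greater-than-zero rule.
    """
    if min_score < 1:
        raise ValueError(f"min_score must be >= 1, got {min_score}")
    scores: dict[tuple[str, str], int] = {}
    n_below = 0
    for rec in records:
        score_to_weight(rec.score)
        if rec.protein_a == rec.protein_b:
            continue
        if rec.score < min_score:
            n_below += 1
            continue
        key = (rec.protein_a, rec.protein_b)
        if key[0] > key[1]:
            key = (key[1], key[0])
        prev = scores.get(key)
        if prev is None or rec.score > prev:
            scores[key] = rec.score
    if n_below:
        logger.info("dropped %d record(s) below min_score=%d", n_below, min_score)
    return WeightedNetwork(scores)


def write_edge_list(network: WeightedNetwork, dest, header: bool = True) -> None:
    """Write the network back to the STRING dialect (one line per edge)."""
    stream, needs_close = (
        (open(os.fspath(dest), "wt"), True)
        if isinstance(dest, (str, os.PathLike))
        else (dest, False)
    )
    try:
        if header:
            stream.write("protein1 protein2 combined_score\n")
        for a, b, s, _ in network.edges():
            stream.write(f"{a} {b} {s}\n")
    finally:
        if needs_close:
            stream.close()
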