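"""Synthetic STRING-dialect networks with planted ground truth.

The generator emits an Erdős–Rényi background over the seed and background
nodes, then wires each planted "connector" node to every seed with a
high-confidence edge.  Connector edges are scored far above the background
band, so the two-hop seed–connector–seed route is strictly cheaper than any
background detour and the connectors are, by construction, the nodes the
shortest-path pipeline should recover.

Connector edge scores carry a small random jitter so that, with several
connectors, different seed pairs prefer different connectors; with identical
scores the deterministic lexicographic tie-break would funnel every pair
through the same connector and the remaining ones would be invisible.

Node identifiers are zero-padded and prefix-grouped (``C`` connectors,
``G`` background, ``S`` seeds), so lexicographic tie-breaks are predictable
in tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["FixtureSpec", "FixtureResult", "FixtureSpecError", "generate_fixture"]


class FixtureSpecError(ValueError):
    """The requested fixture cannot guarantee its planted ground truth."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-connector network.

    Defaults produce the scaled study conditions used throughout the test
    suite: a 2000-node background at mean degree ~12 with mid-confidence
    scores (500–600 band, edge weights 400–500), 36 seeds, and two
    connectors scored so the seed–connector–seed route (weight 600–608)
    undercuts every two-edge background detour (>= 800) but not a single
    background edge.  Seed pairs therefore route through a connector unless
    they happen to share a direct background edge, while random traffic
    gains nothing from the corridor unless it saves two or more hops —
    which keeps the planted truth identifiable under the permutation null.
    """

    n_background_nodes: int = 2000
    background_edge_prob: float = 0.006
    n_seeds: int = 36
    n_connectors: int = 2
    connector_score: int = 700
    background_score_range: tuple[int, int] = (500, 600)
    connector_score_jitter: int = 4
    rng_seed: int = 0

    def validate(self) -> None:
        lo, hi = self.background_score_range
        if self.n_seeds < 2:
            raise FixtureSpecError(f"n_seeds must be >= 2, got {self.n_seeds}")
        if self.n_connectors < 0:
            raise FixtureSpecError("n_connectors must be >= 0")
        if self.n_background_nodes < 0:
            raise FixtureSpecError("n_background_nodes must be >= 0")
        if not 0 <= self.background_edge_prob <= 1:
            raise FixtureSpecError("background_edge_prob must lie in [0, 1]")
        if not (0 < lo <= hi <= 1000):
            raise FixtureSpecError(
                f"background_score_range {self.background_score_range} must lie "
                "within (0, 1000]"
            )
        if not 0 < self.connector_score <= 1000:
            raise FixtureSpecError("connector_score must lie in (0, 1000]")
        if self.connector_score_jitter < 0:
            raise FixtureSpecError("connector_score_jitter must be >= 0")
        # Worst-case connector route must undercut the cheapest possible
        # two-edge background detour: 2*(1000 - (cs - jitter)) < 2*(1000 - hi),
        # equivalently cs - jitter > hi.
        min_conn_score = self.connector_score - self.connector_score_jitter
        if min_conn_score <= hi:
            raise FixtureSpecError(
                "planted routes not guaranteed: worst seed-connector-seed "
                f"weight {2 * (1000 - min_conn_score)} must be < the cheapest "
                f"two-edge background detour {2 * (1000 - hi)}; require "
                f"connector_score - jitter ({min_conn_score}) > max background "
                f"score ({hi})"
            )


@dataclass(frozen=True)
class FixtureResult:
    """Generated fixture: edge-list text plus the planted identities."""

    edge_text: str
    seeds: tuple[str, ...]
    connectors: tuple[str, ...]
    background: tuple[str, ...] = field(repr=False, default=())

    def write(self, out_dir) -> dict[str, Path]:
        """Write edges.tsv / seeds.txt / connectors.txt into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "edges": out / "edges.tsv",
            "seeds": out / "seeds.txt",
            "connectors": out / "connectors.txt",
        }
        files["edges"].write_text(self.edge_text)
        files["seeds"].write_text("".join(f"{s}\n" for s in self.seeds))
        files["connectors"].write_text("".join(f"{c}\n" for c in self.connectors))
        return files


def _names(prefix: str, count: int, min_width: int = 2) -> list[str]:
    width = max(min_width, len(str(max(count - 1, 0))))
    return [f"{prefix}{i:0{width}d}" for i in range(count)]


def generate_fixture(spec: FixtureSpec) -> FixtureResult:
    """Deterministically generate a planted-connector STRING-dialect network.

    Background (Erdős–Rényi) edges span the seed and background nodes with
    scores uniform over ``background_score_range``; each connector is wired
    to every seed with score ``connector_score`` minus a uniform jitter in
    ``[0, connector_score_jitter]``.  Connectors receive no background edges.
    Byte-identical output for identical specs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    seeds = _names("S", spec.n_seeds)
    background = _names("G", spec.n_background_nodes, min_width=4)
    connectors = _names("C", spec.n_connectors)

    er_nodes = seeds + background
    m = len(er_nodes)
    edges: list[tuple[str, str, int]] = []
    if m >= 2 and spec.background_edge_prob > 0:
        iu, ju = np.triu_indices(m, k=1)
        mask = rng.random(iu.size) < spec.background_edge_prob
        lo, hi = spec.background_score_range
        scores = rng.integers(lo, hi + 1, size=int(mask.sum()))
        for i, j, s in zip(iu[mask], ju[mask], scores):
            edges.append((er_nodes[i], er_nodes[j], int(s)))
    if spec.n_connectors and spec.n_seeds:
        jitter = rng.integers(
            0, spec.connector_score_jitter + 1, size=(spec.n_connectors, spec.n_seeds)
        )
        for ci, c in enumerate(connectors):
            for si, s in enumerate(seeds):
                edges.append((c, s, spec.connector_score - int(jitter[ci, si])))

    edges = [(a, b, s) if a < b else (b, a, s) for a, b, s in edges]
    edges.sort()
    buf = io.StringIO()
    buf.write("protein1 protein2 combined_score\n")
    for a, b, s in edges:
        buf.write(f"{a} {b} {s}\n")
    return FixtureResult(
        edge_text=buf.getvalue(),
        seeds=tuple(seeds),
        connectors=tuple(connectors),
        background=tuple(background),
    )
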