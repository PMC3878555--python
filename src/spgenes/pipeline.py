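"""End-to-end pipeline: edge list + seeds -> candidate gene table.

``run_pipeline`` is a plain composition of the module operations — parse,
build, map seeds, seed-pair paths, restricted betweenness, permutation FDR,
filter — with every intermediate written to disk in a deterministic order.
All randomness flows from the single ``rng_seed`` in the configuration, so
two identical runs produce byte-identical tables (only the manifest
timestamp differs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .network import ParseStats, WeightedNetwork, build_network, parse_edge_list
from .paths import (
    BetweennessTable,
    PathRecord,
    SeedSet,
    map_seeds,
    restricted_betweenness,
    seed_pair_paths,
)
from .permutation import (
    PermutationConfig,
    filter_candidates,
    permutation_fdr,
    write_candidates,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "read_seed_file", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs; see the CLI for the matching flags."""

    network_path: str
    seed_path: str
    output_dir: str
    min_score: int = 1
    n_permutations: int = 500
    fdr_threshold: float = 0.01
    rng_seed: int = 0
    write_matrix: bool = False
    log_level: str = "INFO"


@dataclass
class RunResult:
    """In-memory view of a finished run plus the files it wrote."""

    network: WeightedNetwork
    seeds: SeedSet
    paths: list[PathRecord]
    betweenness: BetweennessTable
    candidates: pd.DataFrame
    passed: pd.DataFrame
    manifest: dict
    files: dict[str, Path] = field(default_factory=dict)


def read_seed_file(path) -> list[str]:
    """One identifier per line; blank lines and ``#`` comments ignored."""
    text = Path(path).read_text()
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_paths_tsv(paths: list[PathRecord], dest: Path) -> None:
    with open(dest, "wt") as fh:
        fh.write("source\ttarget\ttotal_weight\tnodes\n")
        for p in paths:
            fh.write(f"{p.source}\t{p.target}\t{p.total_weight}\t{'|'.join(p.nodes)}\n")


def _write_betweenness_tsv(
    table: BetweennessTable, seeds: SeedSet, dest: Path
) -> None:
    rows = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(dest, "wt") as fh:
        fh.write("node\tbetweenness\tis_seed\n")
        for node, count in rows:
            fh.write(f"{node}\t{count}\t{node in seeds.mapped}\n")


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full analysis and write all artifacts into ``output_dir``.

    Raises on unreadable inputs, malformed edge lists, or fewer than two
    mapped seeds; the CLI maps those to a nonzero exit status.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stats = ParseStats()
    records = parse_edge_list(config.network_path, stats=stats)
    network = build_network(records, min_score=config.min_score)
    logger.info(
        "network: %d nodes, %d edges (from %d records)",
        network.n_nodes,
        network.n_edges,
        stats.n_records,
    )

    seed_ids = read_seed_file(config.seed_path)
    seeds = map_seeds(network, seed_ids)
    logger.info("seeds: %d mapped, %d unmapped", len(seeds.mapped), len(seeds.unmapped))

    paths = seed_pair_paths(network, seeds)
    betweenness = restricted_betweenness(paths, network)

    perm_config = PermutationConfig(
        n_permutations=config.n_permutations,
        fdr_threshold=config.fdr_threshold,
        rng_seed=config.rng_seed,
    )
    if config.write_matrix:
        candidates, matrix = permutation_fdr(
            network, seeds, betweenness, perm_config, keep_matrix=True
        )
    else:
        candidates = permutation_fdr(network, seeds, betweenness, perm_config)
        matrix = None
    passed = filter_candidates(candidates, perm_config)

    files: dict[str, Path] = {}

    files["network_summary"] = out / "network_summary.tsv"
    with open(files["network_summary"], "wt") as fh:
        fh.write("key\tvalue\n")
        for key, value in [
            ("n_nodes", network.n_nodes),
            ("n_edges", network.n_edges),
            ("n_records", stats.n_records),
            ("dropped_self_loops", stats.n_self_loops),
            ("dropped_nonpositive_scores", stats.n_nonpositive),
            ("header_skipped", stats.header_skipped),
            ("min_score", config.min_score),
        ]:
            fh.write(f"{key}\t{value}\n")

    files["seed_mapping"] = out / "seed_mapping.tsv"
    with open(files["seed_mapping"], "wt") as fh:
        fh.write("identifier\tstatus\n")
        for s in seeds.mapped:
            fh.write(f"{s}\tmapped\n")
        for s in seeds.unmapped:
            fh.write(f"{s}\tunmapped\n")

    files["paths"] = out / "paths.tsv"
    _write_paths_tsv(paths, files["paths"])

    files["betweenness"] = out / "betweenness.tsv"
    _write_betweenness_tsv(betweenness, seeds, files["betweenness"])

    files["candidates_all"] = out / "candidates_all.tsv"
    write_candidates(candidates, files["candidates_all"])
    files["candidates_pass"] = out / "candidates_pass.tsv"
    write_candidates(passed, files["candidates_pass"])

    if matrix is not None:
        files["permutation_matrix"] = out / "permutation_matrix.tsv"
        matrix.to_csv(files["permutation_matrix"], sep="\t", index_label="permutation")

    manifest = {
        "tool": "spgenes",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": {
            "network_path": os.fspath(config.network_path),
            "seed_path": os.fspath(config.seed_path),
            "output_dir": os.fspath(config.output_dir),
            "min_score": config.min_score,
            "n_permutations": config.n_permutations,
            "fdr_threshold": config.fdr_threshold,
            "rng_seed": config.rng_seed,
            "write_matrix": config.write_matrix,
        },
        "inputs": {
            "network_sha256": _sha256(config.network_path),
            "seeds_sha256": _sha256(config.seed_path),
        },
        "results": {
            "n_nodes": network.n_nodes,
            "n_edges": network.n_edges,
            "n_mapped_seeds": len(seeds.mapped),
            "n_unmapped_seeds": len(seeds.unmapped),
            "n_seed_pairs_connected": len(paths),
            "n_shortest_path_genes": int(len(candidates)),
            "n_candidates_passing": int(len(passed)),
        },
    }
    files["manifest"] = out / "run_manifest.json"
    files["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")

    return RunResult(
        network=network,
        seeds=seeds,
        paths=paths,
        betweenness=betweenness,
        candidates=candidates,
        passed=passed,
        manifest=manifest,
        files=files,
    )
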