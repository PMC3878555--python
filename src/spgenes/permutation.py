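"""Permutation null for restricted betweenness and the candidate filter.

High betweenness alone can reflect network topology (a cut vertex collects
paths whatever the seeds are), so each shortest-path gene is compared against
random seed sets of the same size.  For gene i,

    FDR_i = count(betweenness_random > betweenness_actual) / n_permutations

with a strict inequality: a permutation whose random betweenness merely ties
the actual value does not count.  The quantity is a per-gene permutation
exceedance fraction; it keeps the name "FDR" used in this method's literature
and is not a multiple-testing-corrected rate.  Candidates are shortest-path
genes (betweenness > 0) with FDR strictly below the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .network import WeightedNetwork
from .paths import BetweennessTable, SeedSet, _pair_path_indices

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationConfig",
    "sample_seed_set",
    "fdr_from_matrix",
    "permutation_fdr",
    "filter_candidates",
    "write_candidates",
]

CANDIDATE_COLUMNS = ["gene", "betweenness", "fdr", "is_seed", "passes"]


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-test settings.

    ``n_permutations`` random same-size seed sets are drawn (500 in the
    original analysis); ``fdr_threshold`` is the strict cut-off (0.01);
    ``rng_seed`` makes the whole run reproducible.
    """

    n_permutations: int = 500
    fdr_threshold: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError(f"n_permutations must be >= 1, got {self.n_permutations}")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError(
                f"fdr_threshold must lie in (0, 1], got {self.fdr_threshold}"
            )


def sample_seed_set(
    network: WeightedNetwork, size: int, rng: np.random.Generator
) -> list[str]:
    """Uniform sample of ``size`` distinct nodes, in sorted order.

    All network nodes are eligible — the actual seed genes are not excluded,
    so a random set can overlap or even equal them.  Deterministic given the
    generator state.
    """
    if size < 1:
        raise ValueError(f"sample size must be >= 1, got {size}")
    if size > network.n_nodes:
        raise ValueError(
            f"sample size {size} exceeds the network's {network.n_nodes} nodes"
        )
    pos = rng.choice(network.n_nodes, size=size, replace=False)
    return [network.nodes[i] for i in sorted(pos)]


def fdr_from_matrix(actual: np.ndarray, random_matrix: np.ndarray) -> np.ndarray:
    """Exceedance fractions from an explicit permutation matrix.

    ``actual`` has one betweenness per gene; ``random_matrix`` is
    (n_permutations x n_genes).  Returns, per gene, the fraction of rows
    strictly greater than the actual value — a multiple of 1/n_permutations
    in [0, 1].
    """
    actual = np.asarray(actual)
    random_matrix = np.atleast_2d(np.asarray(random_matrix))
    if random_matrix.shape[1] != actual.shape[0]:
        raise ValueError(
            f"matrix has {random_matrix.shape[1]} gene columns, "
            f"expected {actual.shape[0]}"
        )
    return (random_matrix > actual).sum(axis=0) / random_matrix.shape[0]


def _permutation_betweenness(
    network: WeightedNetwork, seed_idx: np.ndarray
) -> np.ndarray:
    """Restricted betweenness over all node indices for one seed set."""
    csr, _ = network.augmented()
    dist = dijkstra(csr, directed=True, indices=seed_idx)
    inner: list[int] = []
    for _, _, path_idx in _pair_path_indices(csr, dist, seed_idx):
        if path_idx is not None and len(path_idx) > 2:
            inner.extend(path_idx[1:-1])
    if not inner:
        return np.zeros(network.n_nodes, dtype=np.int64)
    return np.bincount(np.asarray(inner), minlength=network.n_nodes)


def permutation_fdr(
    network: WeightedNetwork,
    seeds: SeedSet,
    actual: BetweennessTable,
    config: PermutationConfig,
    keep_matrix: bool = False,
):
    """Permutation FDR for every shortest-path gene.

    Each permutation draws ``len(seeds.mapped)`` random nodes, reruns the
    seed-pair path / betweenness pipeline on them, and compares each gene's
    random betweenness with its actual value.  Permutation ``p`` uses an RNG
    substream seeded by ``(rng_seed, p)``, so results do not depend on
    execution order.

    Returns a :data:`pandas.DataFrame` with columns gene, betweenness, fdr,
    is_seed, passes, sorted by ascending fdr, descending betweenness, gene;
    with ``keep_matrix=True`` also returns the full permutations-by-genes
    betweenness matrix for audit.
    """
    genes = [n for n in network.nodes if actual.counts[n] > 0]
    gene_idx = np.array([network.index(g) for g in genes], dtype=np.int64)
    actual_at = np.array([actual.counts[g] for g in genes], dtype=np.int64)
    k = len(seeds.mapped)

    exceed = np.zeros(len(genes), dtype=np.int64)
    matrix_rows: list[np.ndarray] = []
    for p in range(config.n_permutations):
        rng = np.random.default_rng((config.rng_seed, p))
        sample = sample_seed_set(network, k, rng)
        seed_idx = np.array([network.index(s) for s in sample], dtype=np.int64)
        bet = _permutation_betweenness(network, seed_idx)
        rand_at = bet[gene_idx] if len(genes) else np.zeros(0, dtype=np.int64)
        exceed += rand_at > actual_at
        if keep_matrix:
            matrix_rows.append(rand_at)

    fdr = exceed / config.n_permutations
    table = pd.DataFrame(
        {
            "gene": genes,
            "betweenness": actual_at,
            "fdr": fdr,
            "is_seed": [g in seeds.mapped for g in genes],
            "passes": (actual_at > 0) & (fdr < config.fdr_threshold),
        }
    )
    table = table.sort_values(
        ["fdr", "betweenness", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)
    if keep_matrix:
        matrix = pd.DataFrame(
            np.vstack(matrix_rows) if matrix_rows else np.zeros((0, len(genes))),
            columns=genes,
        )
        return table, matrix
    return table


def filter_candidates(table: pd.DataFrame, config: PermutationConfig) -> pd.DataFrame:
    """Rows passing the filter: betweenness > 0 and fdr strictly below the
    threshold (fdr == threshold fails)."""
    keep = (table["betweenness"] > 0) & (table["fdr"] < config.fdr_threshold)
    return table.loc[keep].reset_index(drop=True)


def write_candidates(table: pd.DataFrame, dest) -> None:
    """Write a candidate table as TSV with fixed 6-decimal FDR."""
    out = table.copy()
    out["fdr"] = out["fdr"].map(lambda x: f"{x:.6f}")
    out.to_csv(dest, sep="\t", index=False)
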