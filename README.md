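# spgenes

Shortest-path candidate gene discovery in confidence-weighted
protein–protein interaction (PPI) networks.

Given a scored interaction network and a set of *seed* genes already known
to be associated with a disease, `spgenes` proposes new candidate genes: the
proteins that sit on the shortest paths *between* the known ones.  The
package ships the 36 curated age-related macular degeneration (AMD) seed
genes as a built-in seed list, and a synthetic-network generator with
planted ground truth so the whole pipeline can be exercised and validated
without downloading an interactome.

## Method

The network is read from a STRING-style edge list
(`protein1 protein2 combined_score`, scores on the integer 0–1000 scale).
Every interaction with score Q > 0 becomes an undirected edge with weight

```
w(u, v) = 1000 − Q(u, v)
```

so high-confidence interactions are short.  For each unordered pair of
mapped seed genes, one canonical Dijkstra shortest path is computed
(ties broken by: minimum total weight → fewest edges → lexicographically
smallest node sequence, with the pair oriented source < target — making
every run bit-reproducible).  The **restricted betweenness** of a node v is
the number of these seed-pair paths that contain v as an inner node; nodes
with betweenness > 0 are the *shortest path genes*.

Because a topologically central node (e.g. a cut vertex) collects paths no
matter where the seeds are, each shortest path gene i is screened by a
permutation test: draw N random node sets of the same size as the mapped
seed set (N = 500 by default), rerun the path/betweenness computation on
each, and report

```
FDR_i = count(betweenness_random,i > betweenness_actual,i) / N
```

with a strict inequality.  Candidate genes are the shortest path genes with
`FDR < 0.01` (strict).  The quantity keeps the name "FDR" used in this
literature; it is a per-gene permutation exceedance fraction, not a
multiple-testing-corrected rate.

## Worked example

Generate a synthetic network with two planted "connector" proteins wired to
all six seeds at high confidence, then run the full pipeline:

```bash
spgenes simulate --out demo/fx --nodes 300 --edge-prob 0.04 \
    --n-seeds 6 --connectors 2 --seed 42
spgenes run --network demo/fx/edges.tsv --seeds demo/fx/seeds.txt \
    --out demo/run --permutations 100 --seed 7
# 2 candidate gene(s) pass (of 2 shortest path genes); outputs in demo/run
```

The candidate table (`demo/run/candidates_pass.tsv`) recovers exactly the
two planted connectors:

```
gene    betweenness    fdr         is_seed    passes
C01     8              0.000000    False      True
C00     7              0.000000    False      True
```

`C01` lies on 8 of the 15 seed-pair shortest paths and `C00` on 7, and in
none of the 100 random same-size seed sets did either node's betweenness
exceed its actual value (fdr = 0).  The per-pair paths are in
`demo/run/paths.tsv` (pipe-delimited node sequences):

```
source  target  total_weight  nodes
S00     S01     604           S00|C00|S01
S00     S02     604           S00|C01|S02
```

Other outputs: `betweenness.tsv` (every node's count), `candidates_all.tsv`
(unfiltered), `network_summary.tsv`, `seed_mapping.tsv`, and
`run_manifest.json` (config, tool version, input checksums).  To analyse a
real STRING protein-links file against the packaged AMD seed list:

```bash
spgenes run --network protein.links.v9.0.txt.gz --amd-seeds --out amd_run
```

`spgenes paths` computes paths and betweenness without the permutation
test; `--write-matrix` dumps the full permutations × genes betweenness
matrix for audit.  Everything is also available as a library
(`spgenes.build_network`, `spgenes.seed_pair_paths`,
`spgenes.permutation_fdr`, ...).

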