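# Methods

## Model and procedure

`spgenes` operates on an undirected graph whose nodes are proteins/genes
and whose edges carry an integer confidence score Q ∈ (0, 1000], the scale
used by STRING-style combined scores.  Edge weight is w = 1000 − Q, so a
path's total weight is low when it chains high-confidence interactions.
Weight 0 (score 1000) is permitted; Dijkstra's algorithm requires only
non-negativity.

The statistic of interest is **restricted betweenness**: for a fixed seed
set S of known disease genes, exactly one canonical minimum-weight path is
computed per unordered pair in S, and a node's betweenness is the number of
those paths on which it appears strictly between the endpoints.  This
differs from classical (Freeman) betweenness centrality in two ways: only
seed pairs contribute, and only one path per pair is counted, so the
maximum attainable value is C(|S|, 2).  Seed genes earn no credit from
their own pair's path but may be inner nodes of other pairs' paths.

Significance is assessed by permutation: N random node sets of size |S|
are drawn uniformly from the whole network (the actual seeds are *not*
excluded, so a random set can overlap or equal them), the path/betweenness
computation is rerun on each, and a gene's reported value is

    FDR_i = #{permutations with betweenness_random,i > betweenness_actual,i} / N.

The inequality is strict and there is no add-one smoothing, so FDR = 0 is
attainable.  Ties between random and actual betweenness — common, because
the statistic is a small integer count — do not increment the numerator,
which makes the fraction anti-conservative relative to the add-one
permutation p-value ((#{≥} + 1)/(N + 1)); the test suite verifies the
strict fraction is bounded by that calibrated quantity.  Candidates are
genes with betweenness > 0 and FDR strictly below the threshold.

## Canonical paths and determinism

Minimum-weight paths are generically non-unique, and betweenness counts
depend on which path is chosen, so the choice is pinned down completely:
minimum total weight, then fewest edges, then the lexicographically
smallest node sequence, with each pair oriented so the source is the
lexicographically smaller endpoint.

Implementation: every edge weight w is mapped to the integer w·K + 1 with
K = node count.  Since any simple path has fewer than K edges, minimising
the augmented distance minimises total weight first and hop count second.
Distances from the seed nodes are computed with
`scipy.sparse.csgraph.dijkstra` on this augmented matrix; augmented
distances are integers below 2^53, so float64 comparisons are exact.  The
lexicographic stage is a greedy forward walk on the shortest-path DAG: from
the current node u, step to the smallest-index neighbour v with
`d_a(v) = d_a(u) + w'(u,v)` and `d_a(v) + d_b(v) = d_a(b)`.  Every such
neighbour lies on an optimal a–b path, so taking the smallest at each step
yields the lexicographically smallest optimal sequence.  Node indices are
assigned in sorted identifier order, making index order and lexicographic
order coincide.

Permutation p uses an independent RNG substream seeded by
`(rng_seed, p)`, so results are identical regardless of execution order,
and a whole run is reproducible byte for byte from its configuration.
Identifiers are opaque strings throughout; no symbol/accession translation
is attempted.

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| `min_score` | 1 | minimum combined score for an edge to exist (1 ⇔ "score > 0") |
| `n_permutations` | 500 | random seed sets drawn for the null |
| `fdr_threshold` | 0.01 | strict cut-off on the exceedance fraction |
| `rng_seed` | 0 | seeds fixture generation and permutation sampling |

With N = 500 the smallest nonzero FDR is 0.002; at the 0.01 threshold a
gene survives only if at most four permutations beat it.  Duplicate edge
records keep the maximum score (conservative toward edge existence;
symmetric duplicates in STRING files are equal-score, so this matters only
for corrupt input).  Self-interactions are dropped — a self-loop can never
lie on a simple path between distinct seeds.  Disconnected seed pairs are
skipped and logged; they contribute nothing to betweenness.

## The synthetic fixture and what it does (not) show

`generate_fixture` emulates the study design at desk scale: an
Erdős–Rényi background over seed + background nodes with scores uniform in
a band, plus planted "connector" nodes wired to every seed at high
confidence.  Defaults (chosen once as the package's study conditions):
2000 background nodes at mean degree ≈ 12, 36 seeds, 2 connectors,
background scores 500–600, connector score 700 with per-edge jitter ≤ 4.

The score geometry is deliberate.  A seed–connector–seed route costs
600–608, strictly below every two-edge background detour (≥ 800) — this is
the generator's validated feasibility condition — but *above* a single
background edge (400–500).  Consequently every seed pair routes through a
connector unless it happens to share a direct background edge (such pairs
take the one-edge path, which has no inner nodes), while random traffic
between background nodes gains nothing from the connector corridor unless
it would save two or more hops.  An earlier design with a near-zero-cost
corridor (connector score ≈ 990) failed this second property: the corridor
became a global shortcut, random seed sets also accumulated connector
betweenness, and the planted truth was not cleanly separable from the null
— the exact confound the permutation test exists to flag.

The per-edge jitter on connector scores exists because the canonical
tie-break is deterministic: with identical connector scores, *every* seed
pair would route through the lexicographically smallest connector and
additional connectors would be invisible (betweenness 0).  Jitter makes
different pairs prefer different connectors, so all planted connectors
acquire betweenness.  A corollary: with two or more equal-scored
connectors and no jitter, "shortest-path genes = connector set" cannot
hold; the exact-recovery guarantee is only closed-form for one connector.

What the fixture does **not** emulate: STRING's heavy-tailed degree
distribution, its evidence-channel structure, score–degree correlation,
or biological modularity.  Passing the planted-recovery tests therefore
shows the machinery is correct and the statistic behaves as designed under
a known truth; it does not certify biological performance on a real
interactome, where betweenness is shaped by hubs and annotation biases.

## Numerical and degenerate-input choices

- Scores are validated to the integer interval (0, 1000]; violations name
  the offending value.  Header lines are auto-detected (third field not an
  integer) and controllable by flag.
- Empty edge lists parse to an empty network; zero or one mapped seed is a
  fatal error (there is nothing to connect).
- The betweenness table always covers every network node, zeros included;
  candidate rows are restricted to betweenness > 0.
- Output tables are sorted deterministically (candidates by ascending FDR,
  then descending betweenness, then identifier) and FDR is printed with
  six decimals.

## Problem sizes

The test suite validates path and betweenness computation by exhaustive
simple-path enumeration on 200 random graphs of up to 10 nodes, and runs
the full-size scaled study — 36 seeds on a ~2000-node network, 630 seed
pairs, 500 permutations — end to end (about 20 seconds on one CPU; the
same study is what `scripts/acceptance.py` reports).  These sizes were
chosen so the entire validation cycle stays interactive while the scaled
study keeps the seed count and permutation count of the original design.

## Known limitations

- One canonical path per pair: genes on co-optimal but non-canonical paths
  receive no credit.  This matches the method's definition (a single
  Dijkstra path per pair) but means betweenness can be sensitive to score
  perturbations when many ties exist.
- The exceedance fraction is a screening statistic, not a calibrated
  p-value; with N permutations its granularity is 1/N, and the strict
  inequality makes it lean small under heavy ties.
- The packaged AMD seed list reflects its curation date (gene symbols as
  curated, e.g. ABCR for ABCA4); mapping identifiers between naming
  systems is out of scope, and unmapped seeds are reported, not translated.
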