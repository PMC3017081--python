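# Methods

This document records the model behind `pathexpand`, the meaning and
defaults of every tunable parameter, what the synthetic benchmark does and
does not emulate, and the numerical conventions the implementation commits
to.  Nothing here claims empirical performance beyond what the shipped code
computes.

## 1. Model and procedure

### 1.1 Mapping

A gene set is a named collection of protein identifiers (GMT format).  Only
members present as nodes of the interaction network take part in any
computation; `map_gene_set` records the mapped subset and its coverage, and
`mapping_report` tabulates coverage across a collection.  Sets with fewer
than `min_set_size` original members, or fewer than 2 mapped members, are
skipped by `extend_collection`.

### 1.2 Candidate filter

For a mapped set `S` on network `G`, candidates are the direct neighbours
of `S` outside `S`.  Candidate `v` is admitted iff

* `deg(v) > 1` (a degree-1 node carries no interconnectedness evidence and
  is disproportionately likely to be a spurious interaction), **and**
* at least one of:
  1. `p(v) / o(v) > T1`, with `p(v)` the number of edges from `v` into `S`
     and `o(v)` the number of edges leaving both `v` and `S`.  When
     `o(v) = 0` and `p(v) > 0` the ratio is treated as infinite and the
     condition passes.
  2. `tri(v) / poss(v) > T2`, where `tri(v)` counts edges from `v` to other
     candidates with which `v` shares a neighbour in `S` (closed triangles
     through the set), and `poss(v) = |N(v) ∩ S| · |N(v) ∩ (C \ {v})|` is
     the number of such triangles that could exist.  `poss(v) = 0` fails
     the condition.
  3. `p(v) / |S| > T3`.

All comparisons are strict.  The full per-candidate ledger (degree, link
counts, triangle counts, which conditions passed) is retained on the
`ExtensionResult` and exported by `diagnostics_table` / `--diagnostics`.

### 1.3 Greedy compactness minimisation

The compactness of node set `X` is

    score(X) = (1 / C(|X|,2)) * Σ_{u<v in X} d(u, v)

with `d` the shortest-path distance in the **full** network (not the
induced subgraph) and unreachable pairs charged a penalty distance `D` (see
§3).  Starting from the mapped set, each round adds the admitted candidate
whose inclusion yields the lowest new score, provided that score is
strictly below the current one; ties between candidates are resolved
towards the lexicographically smallest identifier.  The loop stops when no
candidate strictly lowers the score.  The score after every round is kept
as `compactness_trajectory`, which is therefore strictly decreasing after
its first entry.

The candidate pool and the filter statistics are computed once against the
original set and never refreshed.  Re-growing the pool would let the
extension drift arbitrarily far from the curated core; anchoring it keeps
every addition justified by direct evidence about the original members.

### 1.4 Deletion/recovery cross-validation

For each eligible set, `ceil(fraction · |S|)` members are deleted uniformly
at random, restricted to members with at least one edge to another
remaining member — eligibility is recomputed after every single deletion,
so the deleted members never disconnect a remaining member from the set
entirely.  The reduced set is extended, and the number of deleted members
among the additions is compared with `n_random` random extensions that draw
the same number of proteins uniformly from the reduced set's candidate
pool.  The pooled p-value is

    pooled_p = #{(set, draw) : random recoveries > method recoveries} / (n_sets · n_random)

Ties count in the method's favour; with small integer recovery counts this
makes the statistic conservative in the other direction, which the test
suite accounts for via the tie-corrected identity
`P(X > Y) + P(X = Y)/2 = 1/2` when the method is replaced by its own null.
A pooled value of 0 is reported together with its resolution
`1 / (n_sets · n_random)`.

Deletion happens once, inside the procedure.  Benchmarks that additionally
hide members *before* the cross-validation confound the measurement: the
pre-hidden members remain in the candidate pool as decoys that random
extensions can hit, and the deleted members are drawn from an already
depleted set.

### 1.5 Semantic similarity validation

Information content of term `t` is `IC(t) = −ln(n_t / N)`, where `n_t`
counts proteins annotated to `t` or any descendant and `N` is the number of
annotated proteins in `t`'s namespace.  The Jiang–Conrath distance is
`d(t1, t2) = IC(t1) + IC(t2) − 2·IC(MICA)` with MICA the common ancestor of
maximal IC among ancestors with non-zero usage; it is mapped to a bounded
similarity `sim = 1 / (1 + d)`.  Two protein sets are compared by averaging
`sim` over all pairs of *distinct terms* annotated to either side (term
union, not per-protein averaging), so duplicated proteins and annotation
multiplicity do not bias the score.  The null draws `|added|` proteins from
the original set's candidate pool excluding the extended membership; the
empirical p-value is the fraction of draws at least as similar as the real
extension.  Sets with no additions, or without a single annotated protein
on one side, are skipped with a log notice rather than reported as zeros.

### 1.6 Enrichment comparison

Over-representation of a gene list in each set uses the hypergeometric
upper tail `P(X ≥ overlap)` (equivalently Fisher's one-sided exact test) on
the universe of network proteins (or a user universe, which must contain
every tested set).  Before- and after-extension p-values form two separate
families, each Benjamini–Hochberg adjusted independently — the after-family
is not penalised for the existence of the before-family.

## 2. Parameters and defaults

| parameter | default | role and rationale |
|---|---|---|
| `t1` | 1.0 | link-ratio threshold; > 1 means the candidate has strictly more edges into the set than out of it, i.e. belongs to the set's community in the strong sense |
| `t2` | 0.1 | triangle-ratio threshold; deliberately permissive because `poss(v)` grows quadratically with neighbourhood size, so even cohesive candidates realise a small fraction of possible triangles |
| `t3` | 0.3 | member-coverage threshold; a candidate touching > 30% of a set is pathway-scale evidence on its own, independent of its outside connectivity |
| `min_set_size` | 10 | smallest original set worth extending; below this the filter statistics are dominated by noise |
| `unreachable_penalty_mode` | `node_count` | penalty distance for unreachable pairs; `node_count` charges `|V|`, which exceeds any realisable path length, `fixed` charges `fixed_penalty` (default 1000) for cross-network comparability |
| `fraction` (crossval) | 0.1 | deleted fraction, quota `ceil(0.1·|S|)` |
| `n_random` | 100 | null draws per set; pooled resolution `1/(n_sets·100)` |

Thresholds are validated at construction (`0 < t2 < 1`, `0 < t3 < 1`,
`t1 > 0`, `min_set_size ≥ 2`).

## 3. Numerical conventions

* All inequalities in the filter and the greedy loop are strict; nothing is
  admitted or added on a tie with the threshold or the current score.
* Greedy ties between equally good candidates go to the lexicographically
  smallest identifier, making the extension order-independent and
  deterministic.
* Distances are computed by breadth-first search from each involved node
  once and cached as a pair-sum that is updated incrementally, so each
  greedy round costs one BFS per new candidate rather than a full
  recomputation.
* The penalty `D = |V|` dominates every finite distance, so connecting a
  disconnected pair always beats any rearrangement of finite distances.
* Descriptive statistics (module `graphstats`) use different conventions on
  purpose: the mean in-set distance averages over *connected pairs only*
  (NaN when none), because a descriptive summary should not be dominated by
  a penalty constant; betweenness is reported unnormalised; eigenvector
  centrality is computed per connected component with unit Euclidean norm
  per component (power iteration, tolerance 1e-8, ≤ 1000 iterations,
  single-node components scored 1.0) and raises rather than silently
  failing on non-convergence.
* Every random procedure takes an integer seed (or a NumPy `Generator`)
  and uses `numpy.random.default_rng`; output files carry provenance
  headers without timestamps, so all outputs are byte-reproducible.

## 4. The synthetic benchmark: what it emulates, what it does not

`simulate` plants communities with a stochastic block model: `k` communities
of size `m` with within-community edge probability `p_in` (default 5 × 20 at
0.3), a pool of background nodes, and probability `p_out` (default 0.01)
for every other pair.  Gene sets are the communities with a fraction of
members hidden; a toy ontology DAG assigns each community a subtree, so
hidden members are annotated like their community and semantic-similarity
validation has signal to find; a "mutated" gene list combines hidden
members with random background for the enrichment comparison.

This captures the one property the method relies on — pathway members are
densely interlinked relative to the background — at a realistic edge
density (expected within-community degree ≈ 6-7, background degree ≈ 2).
It does **not** reproduce the heavy-tailed degree distribution of real PPI
networks, hub proteins shared between pathways, overlapping pathway
membership, experimental false positives concentrated on well-studied
proteins, or annotation depth heterogeneity in real ontologies.  Benchmark
numbers therefore bound what the method does under its own model
assumptions; they are not a forecast of recovery rates on curated pathway
databases.

Problem sizes exercised by the shipped tests and benchmark: networks of
~200 nodes / ~1200 edges (planted benchmark), exhaustive brute-force
cross-checks on hundreds of random graphs of ≤ 12 nodes, and topology
oracles on graphs of ≤ 30 nodes.  The implementation is pure Python on
`networkx`; extension of one set is O(rounds · candidates · BFS) and has
been run comfortably on the benchmark sizes above.  Very large networks
(10⁵+ edges) would make the per-round BFS and the full-network betweenness
descriptor the bottlenecks.

## 5. Limitations

* The filter sees only the binary interaction graph: no edge confidence
  weights, no directionality, no complex membership.
* The greedy loop optimises compactness only; a candidate passing the
  filter but not reducing mean distance is never added, so recall on
  sparsely attached true members is deliberately sacrificed for precision.
* The candidate pool is one hop from the original set; members two hops
  away are unreachable by construction.
* Empirical p-values are bounded below by their resolution
  `1/(n_sets · n_random)`; reported zeros mean "below resolution", not
  literal impossibility.
* Jiang–Conrath IC depends on the annotation corpus supplied; comparing
  similarity values across different corpora is not meaningful.
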