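# Methods

## Model and procedure

The pipeline treats a PPI network as an undirected, unweighted simple graph
over opaque protein identifiers. Self-loops are dropped on input (the index
definitions assume simple graphs) and parallel records are deduplicated.
Isolated nodes are representable and retained throughout.

**Mediators.** Given two disjoint disease-protein sets A and B, a two-step
mediator is a node m ∉ A ∪ B with at least one neighbour in each set. By
default m must additionally bridge at least one (a, b) pair with no direct
a–b edge (`require_pair_unlinked=True`) — the mediator connects proteins
that are otherwise unconnected. Turning the flag off admits every
two-sided contact and is exposed for sensitivity analysis. Longer mediator
chains (paths of length ≥ 3) are deliberately not considered.

From a mediator set, the *mediator network* is the induced subgraph on the
mediators plus all of their direct neighbours, and the *mediator
subnetwork* is the induced subgraph on the mediators alone. Whether
neighbour–neighbour edges belong in the mediator network is genuinely open
(either is computable from the same primitive); the induced subgraph —
which keeps them — is the default, since discarding them would misstate
every distance- and walk-based index on the network. The aggregate of the
per-pair mediator networks ("total network") is a plain node/edge-wise
union.

**Indices.** Six per-node indices with the conventions:

* `nD = D_i/(N−1)`; `nBC` is pair-normalized betweenness (factor
  `2/((N−1)(N−2))`); with N < 3 betweenness is all zeros.
* `nCC` on a connected graph is `(N−1)/Σ_j d_ij`. On disconnected graphs
  the Wasserman–Faust variant is used:
  `((r−1)/(N−1)) · ((r−1)/Σ_{reachable} d)`. This matters for the ER null
  ensembles, whose replicates at the analysed densities are always
  disconnected; the choice is visible mainly in the nCC rows of the null
  summaries and is reported, not hidden.
* `TI^n`: the one-step effect matrix is `a₁ = D⁻¹A` (row i scaled by
  1/D_i, zero row for isolated nodes), `a_m = a₁^m` by sparse matrix
  power, `TI^n_i` the average over m = 1..n of column sums of `a_m`.
  Because every row of `a_m` sums to 1 (each node receives unit effect),
  `Σ_i TI^n_i = N` on graphs without isolated nodes — a conservation law
  the tests enforce.
* `TO^n_t` uses the cumulative averaged effect `E = (Σ_{m≤n} a_m)/n`,
  mirroring TI's "up to n steps" convention; a switch
  (`use_cumulative=False`) selects the pure n-step matrix `a_n` instead.
  Strong interactors are selected by strict `>` against the threshold in
  double precision, with no epsilon; the diagonal of E is excluded, so a
  node is never its own strong interactor and the endpoints i, j drop out
  of `S_i ∩ S_j` automatically. Overlaps are raw integer counts, not
  normalized by network size (the summed values on thousand-node networks
  are large integers by design).
* Isolated nodes take 0 for every index.

Degree, closeness and betweenness are standard and are delegated to
igraph's C implementations (betweenness via Brandes' algorithm); the test
suite checks them against brute-force path enumeration and BFS distance
sums on every connected graph of ≤ 6 nodes, and TI against explicit walk
enumeration, all to 1e−12.

**Rank correlations and the null model.** Index pairs are compared by
tie-corrected Spearman rho (Pearson on mid-ranks). A correlation with a
constant input is undefined and reported as missing (NaN), never coerced
to 0. The null model is G(N, p) with `p = L/((N²−N)/2)`; each replicate is
drawn independently, all N nodes kept (isolated ones included, zero-value
convention). Per replicate all six indices and all 15 pairwise
correlations are recomputed; the summary per pair is the mean and the
percentile (2.5th/97.5th) 95% interval — a percentile interval, not a
normal approximation, since nothing guarantees symmetry at small
replicate counts. Replicates with an undefined correlation are excluded
pair-wise with a logged count.

**Enrichment.** Top-k selection (default k = 30) sorts by index value
descending with ties broken by ascending protein identifier, so rankings
are reproducible. Term ratios are simple fractions of the top-k list.
Over-representation uses the one-sided hypergeometric tail (observed-or-
more annotated members in a draw of k from the background, by default the
analysis network's node set, selectable). Per-protein p-values — needed to
correlate functional fit with the indices — aggregate the term-level
p-values of the protein's terms within the evaluated set; the minimum is
the default, mean and Fisher combination are options. Raw p-values are
reported by default; Benjamini–Hochberg adjustment is available as an
explicit step.

## Synthetic data: what it emulates and what it does not

The generator stands in for a curated interactome extract plus a disease
catalogue. Defaults define the study conditions: a 2000-node, 3500-edge
background (mean degree ≈ 3.3, the density regime of the real mediator
networks) grown by preferential attachment — heavy-tailed, left-skewed
index distributions with few extreme hubs — with disease sets of 9 (H),
44 (D) and 20 (O) proteins and planted mediators 16 HD-only, 3 HO-only and
9 shared, reproducing the published bookkeeping (25 HD, 12 HO, 28
distinct). A configuration-model background with power-law degrees is the
alternative; a request of N−1 edges yields the attachment tree.

Planting picks low-degree disease proteins at pairwise distance ≥ 3 where
feasible, removes every direct edge between the two sets of a bridged
pair, wires each planted mediator into both sides of its pair(s), and then
rewires any *accidental* mediator motif away (removing its contacts to the
non-shared disease side and compensating with an edge to a plain node).
Plain–plain edges are trimmed to offset additions, keeping the density
near the request. The result is exactly recoverable ground truth —
`find_mediators` returns precisely the planted sets — which is what makes
precision/recall statements meaningful. Annotations are independent
Bernoulli draws at a 5% base rate per (protein, term); for the designated
enriched terms the odds are multiplied by `enrichment_odds` (default 10)
on planted mediators.

Passing tests on these instances show the pipeline's bookkeeping,
numerics and statistical machinery are correct under realistic size,
density and skew. They do not show anything about a real interactome's
biology: the generator does not reproduce the real degree-distribution
shape, interaction confidence, correlated annotation structure, or the
hub-positioning of real mediators (planted mediators are ordinary nodes,
so synthetic mediator networks are far smaller than their real
counterparts, whose mediators are hubs with thousands of neighbours).

## Numerical and design choices

* Effect matrices in double precision, sparse CSR; matrix powers by
  repeated multiplication (n is small, 3 by default).
* Deterministic ordering everywhere: node tables sorted by identifier,
  canonical sorted edge-list output, fixed column orders — byte-identical
  reruns under a fixed seed, which the pipeline test enforces.
* All randomness flows from one root seed split per stage/replicate via
  `numpy.random.SeedSequence`, so stages can be re-run in isolation.
* Degenerate inputs: empty files parse to empty networks; N < 2 raises for
  degree/closeness; N < 3 raises for the full index table; empty mediator
  sets yield empty networks and all-zero summary rows.
* Null-ensemble sizes: the published analysis used 1000 replicates; the
  package defaults to 1000 while the reproduction script and the test
  suite use 100 replicates per ensemble (the ensemble-mean Monte-Carlo
  error at 100 replicates is ≈ 0.001–0.01, far below the comparison
  tolerance of 0.05).

## Known limitations

* Only the G(N, p) null is provided — no degree-preserving
  (configuration-model) randomization, so "observed below null" statements
  conflate degree heterogeneity with all other structure.
* TO's threshold comparison is exact in floating point; values of E within
  machine epsilon of t are classified by the raw comparison.
* The enrichment stage does no ontology-graph reasoning (no term ancestry
  propagation); terms are opaque labels.
* Closeness on disconnected graphs is one convention among several;
  ensemble nCC means shift by a few hundredths under alternatives such as
  component-restricted closeness.
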