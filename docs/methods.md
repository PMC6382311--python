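# Methods

## Model and procedure

`unicovex` treats a cancer cohort as a binary gene×sample mutation
matrix: multiplicity within a gene–sample pair is discarded, because
the exclusivity model asks only whether a gene is mutated in a sample.
The sample universe is fixed by the mutation file, never by a network:
genes absent from a network cannot join that network's modules, but
their samples still count in every coverage denominator, and samples
whose mutations are all filtered away remain in the cohort and are
reported as uncoverable downstream.

The search is constrained by a gene influence network — either
supplied as a weighted edge list or derived from an unweighted PPI
graph by the insulated heat-diffusion (random walk with restart)
process: with $W$ the column-normalised adjacency and $\beta$ the
restart probability, the influence matrix is
$\beta\,(I-(1-\beta)W)^{-1}$. The directed matrix is row-stochastic in
the influence-of-$i$-on-$j$ orientation; undirected edge weights are
the minimum of the two directed influences (configurable: min, max or
mean — minimum is the conservative choice requiring mutual
influence). Isolated nodes have no defined walk and are dropped with a
warning.

The network is reduced by a single global weight cutoff keeping the
$\lceil d\cdot|V|/2\rceil$ heaviest edges for target average degree
$d$ (default 15, the typical average degree of a curated PPI network).
All edges tied with the threshold weight are retained, so the achieved
degree can slightly exceed the target; the reduction is idempotent and
never adds edges. A per-node top-$k$ rule was rejected because it is
not expressible as removing globally small-weight edges.

Local networks are bounded BFS neighbourhoods (default 100 genes) of
the reduced network. Traversal order is fully specified for
determinism: within each expansion, unvisited neighbours are enqueued
by descending edge weight from the discovering node, ties broken
lexicographically.

Greedy growth starts from each seed gene present in both the reduced
network and the recurrence-filtered matrix (genes mutated in ≥ 2
samples). At each step the pool gene maximising the exclusive score
Ex of the *grown* module is added — this reading (rather than the
candidate's own exclusive degree) matches the stopping rule, which
compares the grown module's Ex to the cutoff. Ties go to the gene
giving the larger union coverage of the grown module, then to the
lexicographically smaller symbol. Growth stops at size 5 or when the
best attainable Ex falls strictly below 0.95 (equality continues).
Every intermediate snapshot of size ≥ 2 enters the catalog;
single-gene modules are excluded because their exclusive entropy, and
hence composite, is identically zero.

Scoring conventions: $0\log 0 := 0$; $H(M) := 0$ when no sample is
exclusively mutated (no exclusive mass carries no balance
information, and the composite is then 0). The composite uses the
*minimum* per-gene coverage; the union coverage is computed and
reported alongside it everywhere, since "module coverage" is commonly
used in both senses. The Dendrix weight
$W(M) = 2|\bigcup_i P_i| - \sum_i n_i$ is reported for comparison
only and never drives selection.

Selection walks each size class in descending composite order,
accumulating modules until every coverable sample of that class is
covered; uncoverable samples are reported, not looped on. Sample-
specific driver prediction is the classic greedy set-cover
approximation run per size group (sizes 2–5 compete separately
because larger modules trivially cover more); ties on marginal gain
go to the higher composite, then lexicographic gene list. The four
size groups are reported side by side, not merged. Consensus across
networks defaults to exact gene-set identity with support ≥ 2;
Jaccard-threshold merging (single-link, transitive, representative =
highest-composite member) is available because cross-network module
identity has no canonical definition.

Evaluation: precision is the fraction of predicted (consensus-union)
genes in the reference list; recall divides by the reference genes
mutated in the cohort. PR/ROC curves sweep a full gene ranking in
which every cohort-mutated gene scores the maximum composite of any
catalog module containing it (0 if none; the zero-score tail is
ordered lexicographically). The ranking rule is a design choice —
score-derived and deterministic — and is the main free parameter of
the curve construction. AUPR uses the step-wise average-precision
convention rather than PR trapezoids, avoiding the optimistic
interpolation bias; average precision is itself slightly positively
biased at small gene universes, which the test suite accounts for
explicitly. ROC AUC is the trapezoid.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_recurrence` | 2 | minimum mutated-sample count for a gene to seed or join modules |
| `local_size` | 100 | genes per BFS local network |
| `max_size` | 5 | maximum module size |
| `ex_cutoff` | 0.95 | strict lower bound on the grown module's Ex |
| `target_avg_degree` | 15 | average degree of the reduced influence network |
| `beta` | 0.45 | diffusion restart probability |
| `min_support` | 2 | networks required for a consensus call |

All defaults are the published operating point of the method; `beta`
0.45 is the standard choice for heat-diffusion influence matrices.

## The synthetic cohort generator

`generate_planted_cohort` emulates the *shape* of the real inputs so
every stage is testable without downloads: a long-tail background
(decoy gene $r$ mutates each sample independently with probability
`passenger_rate` · $r^{-\alpha}$, $\alpha$ = 2 by default), planted
exclusive modules, and a weighted network embedding them. Samples are
partitioned into per-module blocks; each covered sample mutates
exactly one module gene, drawn from a configurable balance
distribution, and with probability `leak_rate` a second module gene is
added (breaking exclusivity). Deterministic-allocation mode apportions
exact largest-remainder counts so entropy worked examples are exact
rather than stochastic. Passenger mutations are restricted to decoy
genes so that `leak_rate` alone controls the planted modules'
exclusivity. Defaults — 200 samples, 300 genes, three planted 4-gene
modules covering 60 samples each, passenger rate 0.02 — give planted
coverages (~15 per gene) and background frequencies in realistic
proportion at desk scale.

Because the sample blocks of different planted modules are disjoint,
genes of *different* modules are mutually exclusive by construction;
no exclusivity-driven score can separate a cross-module mixture from
a true module. The network supplies that information on real data, so
the generator wires each planted module as a heavy clique in its own
graph component (decoys split across components, light random edges
within each). Recovery experiments therefore demonstrate that the
network-constrained greedy search identifies planted structure; they
do not demonstrate robustness to cross-pathway co-occurrence, nor do
the simulations model mutational signatures, hypermutators, copy-number
events or expression-based filtering of the gene universe — all of
which are data-preparation concerns upstream of this package.

With the 0.95 cutoff and 4-gene modules, recovery degrades over leak
rates in roughly the 0–0.1 range: a leak rate beyond ~0.1 pushes a
module's Ex below the cutoff, so growth stops before the full module
forms. The recovery sweep in the acceptance suite uses that grid.

## Numerical and degenerate-input choices

- Entropy and Ex are exact rational arithmetic in floating point; all
  reference values (2.0, 1.75, 6) are reproduced exactly.
- Duplicate undirected edges on ingest keep the larger weight; the
  in-memory network forbids duplicates, self-loops, negative or
  non-finite weights.
- An empty catalog (no eligible seed), zero-gene matrices after
  filtering, and uncoverable samples are all legal states that
  propagate as empty results plus warnings, never exceptions.
- Every tie-break in the pipeline (growth, selection, set cover,
  consensus representatives, rankings) ends in a lexicographic
  comparison, making the whole pipeline deterministic: two runs with
  the same configuration produce byte-identical catalog, cover and
  consensus files. The only randomness in the package lives behind the
  generator's mandatory seed.

## Problem sizes

The test and acceptance suites run at desk scale by design: oracle
equivalence uses 200 random instances of ≤ 10 genes × ≤ 12 samples
(where brute-force enumeration is exact), recovery uses the default
200-sample/300-gene cohorts, and end-to-end runs use 50–80 gene
cohorts with two networks. Full-cohort analyses (thousands of samples,
10⁴ genes, three published interaction networks) use the same code
paths; only the inputs differ.

## Known limitations

- The greedy growth is order-dependent by construction; it recovers
  strictly exclusive modules well but can miss modules whose Ex dips
  below the cutoff mid-growth (the cutoff is strict).
- The set-cover step returns the greedy sequence, not an optimal
  cover; the suite verifies the classic $(1+\ln n)$ bound against
  brute force at small scale.
- Consensus by exact gene-set identity is strict; near-identical
  modules from different networks need the Jaccard mode to merge.
- Gene symbols are taken verbatim: no alias mapping is attempted.
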