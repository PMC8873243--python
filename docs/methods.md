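# Methods

## The model

`netperturb` treats a missense mutation as an *edgetic* event in a
structurally resolved protein–protein interaction (PPI) network: an
undirected graph whose edges carry the interface residues (1-based UniProt
positions) on each partner, and whose proteins carry a per-residue 3D
location label.  Labels come from two sources:

* **Relative solvent accessibility (RSA).**  A residue with RSA < 5% is
  core; RSA > 15% is surface; the 5–15% band is ambiguous and excluded
  from analysis.  When a residue appears in several structure chains, the
  final label is the strict majority over per-chain core/surface calls
  (ambiguous votes discarded; exact ties stay unresolved).
* **Interface membership.**  Any position in the interface set of a
  retained interaction is labelled interface, overriding the RSA label —
  interfaces are by construction solvent-accessible regions that the RSA
  rule would otherwise call surface (or occasionally core).

Interactions with fewer than five distinct interface residues on either
partner are removed before the network is built: an interface supported by
fewer residues on one side is unlikely to be a well-formed physical
contact.  Residues that appear only in interface sets of removed
interactions revert to their RSA-derived labels.  Self-interactions are
excluded by default (centrality semantics of self-loops are ill-defined);
a flag re-admits them.

The perturbation rule maps a mutation to the set of edges it can destroy:
core mutations destabilise the protein and sever all of its interactions;
interface mutations sever exactly the interactions whose interface set (on
the mutated protein) contains the position; surface non-interface
mutations sever nothing.  Gain of new edges is deliberately not modelled.
Nodes are never removed — only edges — so the network order n is constant
and normalised centralities are comparable before and after perturbation.

## Features

Per mutation, 16 network features (and optionally an external block of 83
amino-acid descriptors, giving 99 in total):

| block | features |
|---|---|
| protein-level (7) | degree, betweenness, closeness, eigenvector, clustering coefficient, load, PageRank of the mutated protein in the intact network |
| residue-level (9) | 3D location (ordinal: core 0, surface 1, interface 2); Δdegree, Δbetweenness, Δcloseness, Δeigenvector, Δclustering, Δload, ΔPageRank (each original − perturbed); percent degree change |

Conventions, chosen where the underlying definitions admit variants:

* Degree is the raw neighbour count (needed for percent degree change;
  monotone-equivalent to the normalised form for tree ensembles).
* Betweenness and load are normalised by (n−1)(n−2)/2 per unordered pair
  (equivalently 1/((n−1)(n−2)) over directed pairs).  Load differs from
  betweenness in how flow splits at branch points: a unit packet is divided
  equally among shortest-path predecessors rather than proportionally to
  path counts; the two coincide on trees (a property test asserts this).
* Closeness uses the reachable-set rescaling ((r−1)/(n−1))·((r−1)/Σd),
  which remains meaningful on the disconnected graphs that perturbation
  creates; isolated nodes score 0.
* Eigenvector centrality is the Perron vector with unit Euclidean norm,
  computed by shifted (A+I) power iteration — the shift prevents the
  period-2 oscillation of plain power iteration on bipartite components.
  Internal convergence tolerance is 1e−10 (L1, scaled by n) with at most
  1000 iterations; the tight tolerance keeps results within 1e−6 of a
  dense eigensolver, which the oracle tests require.
* PageRank uses damping 0.85, uniform teleport, uniform dangling
  redistribution, tolerance 1e−9, at most 100 iterations; scores sum to 1.
* The change sign is original − perturbed, so positive values mean
  centrality *loss*.

Mutations that cannot be placed (protein absent from the network,
unannotated position, or the ambiguous RSA band) are unscoreable: they are
skipped and reported through a coverage fraction, mirroring the inherent
coverage limitation of structure-dependent annotation.

### Numerical implementation

Edgetic featurization recomputes centralities on an edge-deleted copy of
the network for every distinct (protein, removed-edge-set) pair, so the
shortest-path measures dominate cost.  They are computed by a single
Brandes-style pass over CSR adjacency arrays that accumulates betweenness
and load simultaneously, JIT-compiled with numba (a pure-Python twin with
identical semantics is the fallback); eigenvector centrality and PageRank
are numpy power iterations on the sparse adjacency; closeness is a single
C-level BFS.  Unit tests pin every measure to networkx to 1e−12
(1e−6 for the iterative spectral measures), and the acceptance suite
additionally checks perturbed values against independent brute-force
oracles (explicit BFS path enumeration, dense linear algebra).
Perturbation results are cached per removed-edge set; all node orders are
sorted, so feature tables are bit-reproducible.

## Classifier protocol

* **Balancing.**  All positives are kept.  Negatives are first capped per
  gene at the median per-gene positive count (rounded to nearest integer),
  preventing any one gene from dominating the negative class, then drawn
  uniformly from the capped pool to reach round(ratio × n_pos) with
  ratio = 4 by default.  The published protocol that inspired this rule
  reports a slightly larger draw than ratio × n_pos without stating the
  exact procedure; the exact-ratio target used here is the documented,
  seedable interpretation.
* **Gene-holdout folds.**  Genes are shuffled (seeded), stably sorted by
  positive count descending, and greedily assigned to the fold with the
  fewest positives (ties: fewest rows, then lowest index) — a
  longest-processing-time-style heuristic that balances classes across
  folds while keeping every mutation of a gene in one fold.
* **Ensemble.**  scikit-learn random forest, 1000 trees, max_features
  'sqrt', one job; per-fold seeds derive from the master seed through
  `SeedSequence([seed, fold])`, decoupling tree randomness from fold
  membership.  The score of a mutation is the fraction of trees voting
  positive.
* **Evaluation.**  Out-of-fold scores are pooled into a single report:
  auROC by the rank-sum identity (ties count 0.5), auPRC by step-wise
  precision–recall integration (no interpolation), and accuracy/F1/MCC
  from the confusion matrix at a 0.5 cutoff (prediction positive when
  score ≥ threshold; MCC defined as 0 when a marginal vanishes).
* **Comparison.**  Paired auROC differences use the DeLong test with
  midrank placements; z follows auroc₁ − auroc₂.  When the placement
  variance is numerically zero the test degenerates: p = 1 for equal
  auROCs (e.g. a scorer against itself), p = 0 with z = ±∞ for a genuine
  difference with zero variance (e.g. perfect vs anti-perfect scorers).
* **Importances.**  Gini (mean decrease in impurity) from a final
  full-data forest, normalised to sum to 1.

## Enrichment statistics

Structural-location enrichment uses two 2×2 Fisher exact tests between a
positive and a negative mutation group: (i) solvent-exposed (surface ∪
interface) versus core, where OR > 1 means the positive group favours the
surface; (ii) among exposed residues only, interface versus plain surface,
where OR > 1 means the positive group favours interfaces.  The odds ratio
is the sample ratio ad/bc (+∞ when bc = 0 with ad > 0); p is the exact
two-sided hypergeometric probability; the 95% CI is the log-OR normal
approximation with the Haldane–Anscombe 0.5 correction when a cell is
empty — the CI construction is a convention choice, made for its ubiquity
in forest-plot style figures.  Group comparisons of feature distributions
use the two-sided Mann–Whitney U test — exact enumeration when both
samples have ≤ 20 tie-free observations, the tie-corrected normal
approximation (no continuity correction) otherwise — with optional
Bonferroni correction over the pairwise comparisons.  Feature correlations
are Pearson; constant columns are reported as missing, never coerced to 0.

## Synthetic data

The generator emulates the study conditions end to end:

* **Topology**: Barabási–Albert preferential attachment (n = 300 proteins,
  attachment m = 2 by default), giving m(n−m) edges and the right-skewed
  degree distribution of real interactomes.  m = 2 matches the mean degree
  (~3.4) of structurally resolved human PPI networks.
* **Interfaces**: 25 distinct positions per edge per endpoint, disjoint
  across a protein's edges while its 500-residue position pool lasts
  (hubs fall back to reuse, which also exercises multi-edge removal).
  The value 25 matches the interface density of the real network this
  emulates (~530k interface residues over ~10.6k interactions ≈ 25 per
  interaction partner); 500 residues is a typical canonical protein
  length.
* **RSA**: remaining positions draw categories core/surface/ambiguous at
  25/60/15% with RSA values uniform inside each band.
* **Labels**: P(positive) = logistic(β₀ + β_deg·z(degree) +
  β_iface·I(interface) + β_core·I(core)) with defaults β₀ = −1.0 (a
  realistic minority positive class of ~35–40%), β_deg = 1.5,
  β_iface = 2.0, β_core = 1.0.  Positions are sampled uniformly over all
  annotated residues, so ambiguous-band mutations occur and exercise the
  coverage path.
* **Amino-acid block**: 83 Gaussian columns; by default 10 are shifted by
  0.5 SD for positives, putting amino-acid-only discrimination in the
  mid-0.8 auROC range typical of published sequence/structure-based
  classifiers.

What the generator does *not* emulate: real amino-acid feature
distributions and correlations, recurrent hotspot clustering within genes,
assortativity and community structure of real interactomes, and
study-bias correlations between degree and annotation depth.  Passing
recovery tests therefore demonstrates that the pipeline extracts planted
network signal correctly — not that equivalent performance would be
attained on real variant sets.

## Problem sizes and known limitations

* The standard recovery run (300 proteins, 2000 mutations, five-fold CV,
  1000-tree forests) was sized to exercise every pipeline stage —
  including ~10³ distinct perturbed-centrality recomputations — while
  completing in about two minutes end to end on a single CPU.
* Reconstructing the published human structurally resolved interactome
  (6230 proteins, 10,615 interactions, 530,668 interface-residue rows)
  requires its supplementary interface table, which is not
  redistributable with the package; the corresponding test runs only when
  the table is placed under `data/`.
* Gini importances split credit among correlated features and favour
  high-cardinality ones: on the synthetic bundle, degree correlates with
  PageRank at r ≈ 0.999, and the continuous proxies (pagerank, load,
  betweenness) absorb the planted degree signal while the small-integer
  degree column ranks low.  This is a property of impurity importances,
  not of the planted model; when degree is the only informative column
  among uncorrelated noise, it ranks first (unit-tested).
* The edgetic model is binary (an edge is removed or kept); partial
  destabilisation, allosteric effects and gained interactions are out of
  scope.
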