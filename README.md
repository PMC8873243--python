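# netperturb

Network-perturbation features for missense variant interpretation.

Most missense variant-effect predictors score a mutation from protein
sequence and structure alone. `netperturb` adds the molecular-interaction
context: it builds a **structurally resolved protein–protein interaction
network** — a PPI graph in which every interaction carries the interface
residues that mediate it, and every residue is classified as buried (core),
solvent-exposed (surface) or interface — and models a mutation as an
**edgetic perturbation**: a core mutation severs all of the protein's
interactions, an interface mutation severs exactly the interactions whose
interface contains the mutated position, and a plain surface mutation
severs none.

From this model the package derives 16 network features per mutation:

* 7 protein-level centralities of the mutated protein — degree,
  betweenness, closeness, eigenvector, clustering coefficient, load,
  PageRank;
* 9 residue-level features — the ordinal 3D location (core 0 / surface 1 /
  interface 2) and, for each centrality *c*, the change
  Δc = c(original) − c(perturbed) after deleting the affected edges, plus
  the percent degree change 100·(deg₀ − deg₁)/deg₀.

These features feed a random-forest classifier (1000 trees, √p candidate
features per split, score = fraction of trees voting positive) evaluated
with **gene-holdout cross-validation** — all mutations of a gene stay in
one fold, so the classifier is always tested on unseen genes.  The package
also provides the accompanying statistics: training-set balancing with a
per-gene cap, Fisher exact odds ratios for structural-location enrichment,
Mann–Whitney group comparisons, Pearson feature correlations, and the
DeLong test for paired auROC differences.  A synthetic-data module
generates scale-free interactomes with planted logistic labelling models so
the whole pipeline is testable end to end.

Intended users: computational biologists studying how interactome
architecture shapes the impact of somatic (driver vs passenger) and
germline (pathogenic vs neutral) missense variation.

## Worked example

```python
from netperturb import (
    Mutation, VariantClassifier, LabeledDataset, featurize, perturb_and_diff,
)
from netperturb.synthetic import generate_bundle

bundle = generate_bundle(n_proteins=300, n_mutations=2000, seed=7)
net = bundle.network

# one mutation, by hand
mut = bundle.mutations[2]
print(mut.protein, mut.position, perturb_and_diff(net, mut).degree_change)

# full pipeline: featurize, cross-validate, summarise
ds = LabeledDataset.from_featurize(featurize(net, bundle.mutations))
results = VariantClassifier(ds, features="net").fit(k=5, seed=0)
print(results.summary())
```

prints (abridged):

```
P0071 176 0.0

Variant classifier (random forest, gene-holdout CV)
===================================================
features: net   folds: 5   seed: 0
rows: 1759  (+662 / -1097)

auROC      0.7634
auPRC      0.7065
accuracy   0.7351  (threshold 0.5)
F1         0.6051
MCC        0.4172

top feature importances (Gini):
  pagerank                      0.1357
  load                          0.1013
  betweenness                   0.1007
  ...
```

The mutation at `P0071:176` is a surface non-interface residue, so its
degree change is exactly 0.  The cross-validated auROC of ~0.76 on
network features alone reflects the planted signal (labels were generated
from protein degree and core/interface location); the Gini importances
concentrate on the protein-level centralities, which carry most of that
signal.

The same steps are available from the shell:

```sh
netperturb simulate --n-proteins 300 --n-mutations 2000 --seed 7 --out bundle/
netperturb build-net --interfaces bundle/interfaces.tsv --rsa bundle/rsa.tsv \
    --out-edges edges.tsv --out-residues residues.tsv
netperturb featurize --interfaces bundle/interfaces.tsv --rsa bundle/rsa.tsv \
    --mutations bundle/mutations.tsv --network-only --out matrix.tsv
netperturb train --matrix matrix.tsv --features net --seed 0 --out metrics.json
netperturb enrich --interfaces bundle/interfaces.tsv --rsa bundle/rsa.tsv \
    --mutations bundle/mutations.tsv --out enrichment.json
```

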