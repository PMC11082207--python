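# revscreen

Ligand-based **reverse screening** (target fishing) for small molecules:
given one query compound, rank candidate protein targets by how similar the
query is to each target's known active ligands. The package implements the
full prediction engine — conformer shape descriptors, path fingerprints,
size-stratified logistic models — together with the validation methodology
that goes with it (success@rank curves, knowledge/diversity stratification,
distinct-set construction, descriptor-space comparison) and a seeded
synthetic-bioactivity generator so every stage is testable without any
database download.

It is written for computational chemists and method developers who want a
transparent, fully scriptable reference implementation of similarity-based
target prediction, from raw activity records to evaluated rankings.

## The model

The engine rests on the similarity principle: structurally similar
molecules tend to share bioactivity. A query molecule *q* is compared to
every known active *a* of a target *T* with two descriptors:

- **3D-Score** — each molecule is represented by up to 20 conformers, each
  encoded as an 18-dimensional ES5D vector: atoms are embedded in 5D
  (x, y, z, scaled partial charge, scaled atomic lipophilicity), six
  centroids are placed, and the first three distance moments to each
  centroid recorded. The score is the Manhattan-based similarity
  `M_s = 1 / (1 + d/18)` where `d` is the smallest L1 distance over all
  conformer pairs; per target the maximum over actives is taken.
- **2D-Score** — the maximum Tanimoto coefficient `T_c = |A∩B| / |A∪B|`
  between 1024-bit linear-path fingerprints (paths of 2–7 atoms).

Because the informativeness of the two scores varies with molecular size,
queries are stratified into 51 heavy-atom classes (≤10, 11…59, ≥60), each
with its own binary logistic model

```
Probability = 1 / (1 + exp(−c1·3D-Score − c2·2D-Score − C))
```

trained on known actives (label 1) versus measured and *alleged* inactives
(label 0) at a 10:1 negative:positive ratio. The per-class coefficient
curves c1, c2, C are smoothed by a degree-3 polynomial in the class id
before prediction. Screening a query against all targets yields one
probability per target; targets are ranked and validated by
**success@rank k**: the fraction of external queries whose experimentally
known target appears within the top k.

## Worked example

`examples/03_planted_reverse_screen.py` builds a small planted universe
(8 targets, one analog series each, 3 held-out analogs per target as
external queries), trains the models and screens the queries:

```
universe: 126 training compounds, 8 targets, 24 queries
size classes fitted: [14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 25, 26]
success@1: 100.0%
success@3: 100.0%
success@8: 100.0%

top-3 predictions for query T00H0 (true target T00):
  #1 T00  p=0.470 3D-Score=0.830 2D-Score=0.773
  #2 T04  p=0.184 3D-Score=0.676 2D-Score=0.343
  #3 T07  p=0.140 3D-Score=0.643 2D-Score=0.240
```

The query's own analog series dominates both similarity features, so its
true target tops the ranking — success@1 of 100% means this held for every
held-out query. The other examples demonstrate the similarity features
(`01`), the curation and labeling rules (`02`) and the descriptor-space /
scaffold comparison (`04`).

A thin CLI mirrors the library for shell use:

```bash
revscreen fixtures --targets 20 --actives 30 --heldout 5 --seed 7 --out fix/
revscreen featurize --in compounds.tsv --conformers 20 --seed 7 --out descr/
revscreen train --set fix/training_set.tsv --descr descr/ --out coeffs.json
revscreen screen --queries queries.tsv --screening fix/training_set.tsv \
                 --coeffs coeffs.json --descr descr/ --out results.tsv
revscreen evaluate --results results.tsv --truth fix/truth.tsv
```

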