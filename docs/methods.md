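# Methods

## Model and assumptions

The engine is a ligand-based (structure-free) target predictor: it never
looks at the protein, only at the similarity between a query molecule and
the known actives of each candidate target. Its central assumption is the
similarity principle — similar molecules tend to share bioactivity — made
operational through two complementary molecular representations and a
calibrated combination of the two.

**Shape (ES5D).** Each molecule is protonation-adjusted, embedded in 3D and
represented by up to 20 conformers. Every conformer becomes a point cloud
in five dimensions: the Cartesian coordinates (Å) plus the Gasteiger
partial charge and the Wildman–Crippen atomic lipophilicity contribution,
both scaled into Å-comparable units. Six reference centroids are placed in
this 5D space — the barycentre; the atom furthest from it; the atom
furthest from that atom; two off-plane points along the cross product of
the two spanning vectors carrying the extreme scaled charges; and the
barycentre carrying the extreme scaled lipophilicity. For each centroid the
mean, standard deviation and sign-preserving cube root of the third central
moment of the atom–centroid distances are stored: 18 floats per conformer,
invariant under rigid rotation and translation. Shape similarity between
two molecules is `M_s = 1/(1 + d/18)` with `d` the smallest Manhattan
distance over all conformer pairs.

**Chemical structure (path fingerprints).** The standardized 2D structure
is hashed into a 1024-bit vector encoding its linear atom paths of 1–6
bonds (2–7 atoms). Structural similarity is the Tanimoto coefficient.
Bit-exact compatibility with any particular external fingerprint tool is
not a goal; the dialect is internally consistent and deterministic across
atom orderings.

**Size-stratified logistic combination.** For a (query, target) pair the
two features are the maxima of `M_s` and `T_c` over the target's actives.
Queries are stratified into 51 heavy-atom classes (≤10 pooled, 11–59
singly, ≥60 pooled) because the relative information content of shape and
substructure similarity shifts with molecular size. Each class gets a
binary logistic model `P = 1/(1 + exp(−c1·s3 − c2·s2 − C))` trained on
active pairs versus a 10:1 mixture of measured inactives (≥ 100 µM) and
*alleged* inactives (compounds never reported active on that target),
sampled per target, uniformly, without replacement and seeded. Gray-zone
pairs (10–100 µM) train neither class. A training query that is itself an
active of the target is excluded from its own comparison. The fitted
coefficient curves over the 51 classes are smoothed with an unweighted
degree-3 polynomial, and prediction uses the smoothed table. At screening
time every target receives a probability and targets are ranked;
probabilities function purely as ranking scores.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| charge scale | 25 | Å per e | the established ElectroShape convention for mixing charge with coordinates |
| lipophilicity scale | 7.5 | Å per log-unit | atomic Wildman–Crippen contributions span roughly −1…+1, so 7.5 puts the dimension's spread on the same footing as atomic coordinates (~±5 Å); configurable because no canonical value exists |
| conformers | 20 (API), 3 in the planted studies | — | conformer count trades shape coverage for cost; the planted analog series differ by small substituents, so few conformers already separate the series |
| activity thresholds | 10 / 100 | µM | actives ≤ 10 µM, inactives ≥ 100 µM, gray in between |
| heavy-atom filter | 5–80 | atoms | curation window for small-molecule data |
| negative:positive ratio | 10:1 | — | standard setting for this model family |
| logistic fit | L2-penalized, C = 1.0 | — | the scikit-learn default estimator; keeps per-class coefficients finite even when a class is linearly separable (`penalty=None` is available for the plain maximum-likelihood fit) |
| smoothing | cubic in class id | — | removes class-to-class fitting noise |
| decision threshold | 0.5 | — | confusion counts (TA/TI/FA/FI) for MCC, precision, recall |

## Numerical choices

- **Degenerate geometries.** Conformers with fewer than three atoms or a
  vanishing cross product (collinear atoms) fall back to duplicating the
  barycentre for the undefined centroids, so the descriptor is always 18
  values; a single atom yields the zero vector.
- **Third moment.** Stored as the sign-preserving cube root, keeping all 18
  components in Å and on comparable scales.
- **Empty fingerprints.** Tanimoto of two empty bit sets is defined as 0.0
  (no evidence of similarity).
- **MCC with a zero denominator factor** is defined as 0.
- **Smoothing outside the fitted range.** The cubic is evaluated with the
  class id clamped to the fitted class range: outside its support a cubic
  extrapolates freely and can even flip coefficient signs, so classes
  without training data inherit the nearest fitted class's smoothed values.
- **Tie-breaking in rankings.** Equal probabilities order by descending
  2D-Score, then descending 3D-Score, then lexicographic target id, making
  ranks fully deterministic.
- **Separable classes.** With the default L2 fit, separable classes get
  finite coefficients; cross-validated metrics are computed per fold at
  threshold 0.5 with folds drawn at the row level (no grouping by molecule
  or target), reshuffled once if a fold ends up single-label.
- **Determinism.** Every stochastic step (conformer embedding, negative
  sampling, fold assignment, universe generation) derives its RNG from an
  explicit seed; per-compound conformer seeds mix the base seed with a CRC
  of the compound id so results are independent of iteration order. All
  file interfaces write floats with 17 significant digits, which
  round-trips IEEE-754 doubles bit-exactly.

## Scaffold definitions

Two abstractions describe chemical diversity:

- **Wire-frame (Bemis–Murcko style).** Side chains are stripped (ring
  systems and linkers retained), then every atom is levelled to carbon and
  every bond to a single bond. Stripping and levelling iterate to a fixed
  point, which guarantees idempotence (the scaffold of a scaffold is
  itself). Acyclic molecules yield the EMPTY scaffold and are excluded
  from scaffold counts but kept in molecule totals.
- **Oprea-style ring/linker graph.** Computed from the wire frame by
  removing residual terminal atoms and contracting every degree-2 non-ring
  linker atom, joining its neighbours directly, until none remain. The
  result is a pure ring-and-junction graph; by construction it is a
  function of the wire frame, so molecules sharing a wire-frame scaffold
  share the abstracted one. String-level compatibility with external
  scaffold tools is not claimed; canonical forms are canonical within this
  package.

The *distinct* subset of an external test set keeps compounds whose
wire-frame **and** abstracted scaffolds both occur in no training molecule
— the conjunction makes the subset robust to either definition's quirks.

## The synthetic universe

`fixtures.generate_universe` emulates the statistical structure the model
assumes rather than any particular database. Each target owns a distinct
hand-written core scaffold; its actives are an enumerated analog series
(core decorated with small substituents on two sites), with activity values
log-uniform in (0.001, 10] µM. Decoys come from reserve cores and carry,
per target, a measured-inactive record (log-uniform 100–10,000 µM) with
probability 0.30, a gray record (10–100 µM) with probability 0.05, or no
record (alleged inactive). Held-out analogs per target form the external
test set and are guaranteed absent from training by standardized canonical
structure. Generation asserts the planted truth: every held-out analog is
strictly closer (max fingerprint Tanimoto) to its own target's actives than
to any other target's. A knowledge-stratification variant gives some
targets only two actives drawn from unrelated cores, modelling proteins
with few, dissimilar known ligands.

What the fixture does **not** emulate: real bioactivity data's assay noise,
activity cliffs, promiscuous scaffolds shared across many targets,
property-matched decoys, tautomer/stereo ambiguity, and the heavy-tailed
distribution of actives per target. Passing the planted studies therefore
demonstrates that the pipeline is correct and well-calibrated on data that
satisfies the similarity principle cleanly — not that a given real-world
success rate will be achieved. Full-scale results on licensed databases
(hundreds of thousands of compounds, thousands of targets) are out of
scope at desk scale by deliberate design; the studies here use 20 targets
× 30 actives × 5 held-out analogs with 3 conformers per molecule as the
package's standard study size.

## Design decisions on open points

- Conflicting measurements for one pair: any value ≤ 10 µM labels the pair
  active, taking precedence over the all-≥100 µM inactive rule (matches
  the gray-area construction).
- Structure identity for overlap removal: equality of standardized
  canonical SMILES, stereochemistry-sensitive; pairs with identical
  fingerprints but different structures/ids are retained.
- Negative sampling is stratified per target (each target's actives get
  their own 10:1 complement) rather than global.
- Multi-target queries are evaluated at their best (minimum) rank, and
  knowledge/diversity bins are assigned by the best-ranked known target.
- The enrichment factor is defined as EF(k) = success-fraction(k)/(k/N)
  with N the number of screened targets; the definition is pluggable.
- No similarity floor is applied when screening; an optional pre-filter
  exists purely as a performance knob and must not change top ranks.

## Known limitations

- The centroid recipe follows the cited descriptor lineage but is not
  bit-compatible with any vendor implementation; absolute `M_s` values are
  therefore package-specific, though rankings are internally consistent.
- Protonation at physiological pH is approximated by RDKit standardization
  rather than a full pKa model.
- Conformer ensembles use distance-geometry embedding with force-field
  ranking; ill-parameterized exotic atoms fall back to embedding order.
- Classes with fewer than 50 training pairs are fitted but should be
  treated as low-confidence (the CV command flags them).
- Z-factor is undefined for exactly equal means and explodes as means
  approach; it is a deliberately harsh separation statistic, strongly
  negative whenever distributions overlap.
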