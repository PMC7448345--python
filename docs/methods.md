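# Methods

## Ontology model and conventions

The ontology is a rooted mono-hierarchy: every non-root concept has exactly
one parent, all parent chains terminate at a single root, and depth is
defined recursively with **depth(root) = 0**. The root-depth convention is
not innocuous: with it, two concepts whose only shared ancestor is the root
have Wu-Palmer distance exactly 1 (maximally unrelated findings), and
siblings at depth 4 under a depth-3 parent have distance 0.25 — the worked
example the package's acceptance checks reproduce. Depths are always
recomputed from the parent links on load, never trusted from a file.

The root is treated as a structural node, not a finding: it is excluded
from the concept index, from patient vectors, and from augmentation.
Including it would add a constant shared component to every patient vector
and compress all cosine distances toward 0.

## Distance metrics

Let A, B be finding sets, a, b binarized vectors over the n non-root
concepts (lexicographic id order everywhere, for deterministic output).

* Jaccard: `1 − |A∩B| / |A∪B|`.
* Cosine: `1 − Σaᵢbᵢ / (‖a‖‖b‖)`; entries are non-negative, so the value
  lies in [0, 1].
* Wu-Palmer concept distance:
  `dist(a, b) = 1 − 2·depth(LCS) / (depth(a) + depth(b))`. In a
  mono-hierarchy this is 0 iff a = b. It is precomputed into an n×n lookup
  table, materialized dense up to n = 2000 and computed lazily (with row
  caching) above that; the lookup contract is identical.
* Augmentation vectors: weight `1/(1 + n)` on the n-th ancestor of each
  concept (n = 0 the concept itself), up to but *excluding* the root;
  descendants are never weighted. Ancestor chains are not truncated at any
  level. A patient's augmented vector is the sum over its findings'
  augmentation vectors, so weights on shared ancestors accumulate
  (a patient with *tremor* and *resting tremor* holds 1 + ½ at the
  *tremor* position). The augmented cosine distance is the plain cosine
  distance of two augmented vectors.
* Augmented bipartite: `(D(A,B) + D(B,A)) / 2` with
  `D(A,B) = (1/|A|) Σ_{a∈A} min_{b∈B} dist(a,b)`. The two directed terms
  are exact mirrors of each other (mean over one set of the minimum into
  the other).

Numerical hygiene: all distances are computed in double precision; values
within 1e-12 outside [0, 1] are clipped and matrices are symmetrized by
averaging with their transpose (any asymmetry at that point is FP noise —
each unordered pair is conceptually computed once). The diagonal is forced
to zero. No triangle inequality is claimed for any metric (cosine distance
violates it), and none is tested.

Duplicate findings collapse on ingestion (patients are sets); severity is
not modelled — findings are present or absent.

## Synthetic cohort generator

The generator emulates the statistical structure of a findings-coded test
group of competing diagnoses, not any particular disease content:

* **Ontology stand-in**: a complete 4-ary tree of depth 4 (340 non-root
  concepts, 256 leaves). This keeps every desk-scale computation fast
  while preserving the depth structure that makes augmentation and
  Wu-Palmer distances non-trivial.
* **Archetypes**: each of 8 diagnoses receives 8 distinct leaf findings,
  sampled with a 4:1 weight bias toward one randomly chosen depth-1
  subtree so a diagnosis's findings cohere semantically. Archetypes may
  overlap across diagnoses; overlap is emergent, not configured —
  mirroring how real competing diagnoses share findings such as weakness.
* **Patients**: 12 per diagnosis. Each patient keeps every archetype
  finding independently with probability `p_core = 0.7` and gains a
  Poisson(`noise_rate = 1.0`) count of uniform-leaf noise findings; empty
  draws are resampled. Expected findings per patient:
  8 × 0.7 + 1 = 6.6, in the realistic range for abstracted case reports
  (≈ 6–7 findings); 8 × 12 = 96 patients per cohort matches a realistic
  test-group size with roughly a dozen patients per diagnosis. Poisson was
  chosen for the noise count because it is the natural single-parameter
  count distribution; only a mean is specified by the design.

All randomness flows from the explicit config seed through a single
`numpy.random.default_rng` stream per generator call; identical configs
produce byte-identical TSV outputs.

**What the generator does not emulate**: real case abstraction (verbatim
findings interpreted by a human abstractor), unbalanced diagnosis
frequencies, severity grading, correlated noise (comorbidities), or the
1204-concept scale of a production ontology. Passing tests on synthetic
cohorts therefore demonstrate correctness of the machinery and the
*qualitative* distance structure (augmented means smaller; within- <
between-diagnosis), not quantitative performance on real patients —
real-data accuracy depends on abstraction quality and inter-diagnosis
finding overlap that the generator only caricatures.

## Evaluation harness

* **Cross-validation**: stratified 10-fold with a fixed seed. Fold
  assignment is a seeded per-class round-robin deal, which keeps per-class
  fold counts within 1 of proportionality and degrades gracefully to
  leave-one-out (sklearn's `StratifiedKFold` rejects classes smaller than
  the fold count, so it is not used).
* **kNN** (k = 5, uniform weighting) consumes the precomputed distance
  matrix directly. Vote ties are broken by the smaller mean distance to
  the tied classes' neighbors, then by lexicographic label — fully
  deterministic.
* **Naive Bayes, logistic regression (L2), random forest (10 trees)**
  cannot consume a distance matrix natively; each patient is represented
  by its vector of distances to the *training* patients of the current
  fold (test rows restricted to training columns, so no leakage). This
  "distance rows as features" reading is the default; a
  `features="binary_findings"` switch substitutes the raw binarized
  finding vectors, since pipelines differ on which representation such
  classifiers should see. The naive Bayes is Gaussian on the continuous
  distance features (a discretizing NB variant is not replicated).
* **Agglomerative clustering** applies the Ward Lance–Williams recurrence
  to the precomputed distances (scipy `linkage(..., "ward")` on the
  condensed matrix) and cuts at 8 clusters. Ward on non-Euclidean
  precomputed distances is mathematically heterodox but is the standard
  practice this harness reproduces; a naive O(n³) Lance–Williams
  implementation serves as an independent cross-check in the tests.
* **k-means** needs coordinates, so the rows of the distance matrix are
  treated as feature vectors; 10 seeded restarts, best inertia kept.
* **Scores**: accuracy and macro F1 (classes never predicted contribute
  0), and for clustering silhouette (on the precomputed distances;
  reported as missing, not 0, when a single cluster makes it undefined),
  adjusted Rand, adjusted mutual information (the adjusted rather than
  normalized variant), homogeneity, completeness and V-measure — all on a
  0–100 scale; ARI/AMI are chance-corrected and may be negative.

## Distance statistics

Per patient, the mean distance to same-diagnosis patients (self excluded)
and to different-diagnosis patients; aggregates are unweighted means over
patients for which the quantity is defined, and a single-member diagnosis
yields a missing within-mean, never 0. The omnibus one-way F across
metrics treats each unordered patient pair as one observation per metric.
**Warning**: pairwise distances sharing a patient are not independent, so
this F is a descriptive effect-size summary, not a calibrated test; it is
reproduced in this form deliberately, and no post-hoc pairwise testing is
attempted. Ordered pairs are not used (the matrices are symmetric, so they
would merely duplicate every observation).

## Problem sizes and determinism

Default analyses run on 96-patient cohorts over 340-concept trees — sizes
chosen so the full pipeline (tables, four matrices, 10-fold evaluation)
completes in seconds while leaving every statistical structure of interest
visible. Property-based checks sweep ~200 random ontology/cohort cases;
chance-level and chance-correction checks average 50 seeded replicates.
Every stochastic step takes an explicit integer seed; there is no hidden
global RNG state, and repeated runs are byte-identical.

## Known limitations

* Binary findings only: no severity, laterality or temporal qualifiers.
* Mono-hierarchies only: poly-hierarchical ontologies (multiple parents,
  SNOMED CT-style) are out of scope, as are other concept-similarity
  measures (Lin, Resnik, path counts, information content).
* The bipartite metric is not a metric in the mathematical sense (no
  triangle inequality), and Ward/k-means on precomputed non-Euclidean
  distances inherit the caveats noted above.
* The synthetic generator's balanced classes make classification easier
  than on real, unbalanced cohorts.
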