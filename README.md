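# ontodist

Ontology-based inter-patient distance metrics — and an evaluation harness
for asking whether *semantic augmentation* of those metrics helps machine
learning tell patients apart.

## The problem

In clinical phenotyping, a patient is often coded as a **set of finding
concepts** (signs and symptoms) drawn from a mono-hierarchical ontology —
a rooted tree in which every concept has exactly one parent, such as a
curated neuro-ontology of UMLS-coded neurological findings. Distances
between such patients drive nearest-neighbor classification and patient
clustering. Standard set/vector metrics treat two different concepts as
simply unequal; semantically augmented metrics instead give partial credit
when two patients carry *similar* findings (e.g. *resting tremor* vs
*postural tremor*, siblings under *tremor*). This package implements both
families and the machinery to compare them.

## The metrics

For patients A, B with finding sets (or binarized finding vectors a, b):

* **Jaccard distance** = 1 − |A∩B| / |A∪B|
* **cosine distance** = 1 − (Σ aᵢbᵢ) / (‖a‖·‖b‖)
* **augmented cosine** — each finding first contributes an
  ancestor-weighted vector with weight 1/(1+n) on its n-th ancestor
  (1 on itself, ½ on its parent, ⅓ on its grandparent, …, root excluded);
  the cosine distance is then taken between the augmented patient vectors
* **augmented bipartite** = (D(A,B) + D(B,A)) / 2 with
  D(A,B) = (1/|A|) Σ_{a∈A} min_{b∈B} dist(a,b), where dist is the
  **Wu-Palmer concept distance**
  dist(a,b) = 1 − 2·depth(LCS) / (depth(a) + depth(b)),
  LCS being the lowest common subsumer in the hierarchy (root depth 0).

All four are symmetric, zero on identical patients, and normalized to
[0, 1]. A seeded synthetic-cohort generator (diagnosis archetypes + noise
over a complete concept tree) supplies test data with the statistical
structure of a real findings-coded cohort, and the evaluation layer runs
four classifiers (kNN on precomputed distances; naive Bayes, L2 logistic
regression, random forest on distance-matrix rows) under stratified 10-fold
CV, plus Ward agglomerative and k-means clustering with the standard
quality indices (silhouette, ARI, AMI, homogeneity, completeness,
V-measure).

## Worked example

```python
import ontodist as od

# the classic sibling example: root -> x -> y -> tremor -> {resting, postural}
o = od.Ontology({"x": "root", "y": "x", "tremor": "y",
                 "resting_tremor": "tremor", "postural_tremor": "tremor"})
od.wu_palmer_distance(o, "resting_tremor", "postural_tremor")   # 0.25
idx = od.ConceptIndex.from_ontology(o)
od.augmentation_vector(o, "resting_tremor", idx)[idx["tremor"]] # 0.5

# synthetic cohort: 8 diagnoses x 12 patients over a 340-concept tree
ontology, cohort = od.simulate(od.SyntheticConfig(seed=7))
res = od.PatientSimilarityModel(cohort).fit()
print(res.summary())
```

```
Ontology-based patient distance analysis
  patients: 96   diagnoses: 8   concepts: 340

                       mean      sd  within_mean  between_mean     gap
metric
jaccard              0.9349  0.1532       0.5500        0.9853  0.4353
cosine               0.9050  0.2027       0.3893        0.9725  0.5833
augmented_cosine     0.8165  0.1971       0.3372        0.8793  0.5421
augmented_bipartite  0.6597  0.1894       0.2602        0.7120  0.4519

one-way F across metrics: 1999.6 (df = 3, 18236)
```

The sibling Wu-Palmer distance is 0.25 (shared parent at depth 3, siblings
at depth 4: 1 − 2·3/8), and an augmented vector puts weight 0.5 on a
finding's immediate parent. In the cohort summary, the augmented metrics
produce systematically *smaller* mean inter-patient distances than their
unaugmented counterparts (augmented bipartite lowest, Jaccard highest),
and every metric places same-diagnosis patients closer together than
different-diagnosis patients (`within_mean < between_mean`) — the gap that
classifiers and clusterers exploit. `res.evaluate(od.EvalConfig(seed=7))`
returns the tidy score table; on this well-separated synthetic cohort all
four metrics classify near-perfectly (e.g. kNN accuracy 100.0 for each),
mirroring the finding that augmentation moves patients closer without
necessarily improving downstream accuracy.

## Command line

```bash
ontodist simulate --seed 7 --outdir run/
ontodist distances --ontology run/ontology.tsv --cohort run/cohort.tsv --outdir run/dist/
ontodist evaluate  --matrices run/dist/ --ontology run/ontology.tsv \
                   --cohort run/cohort.tsv --outdir run/eval/
ontodist report    --matrices run/dist/ --ontology run/ontology.tsv \
                   --cohort run/cohort.tsv --outdir run/report/
```

Each stage writes a `manifest.json` (config, seeds, input digests,
timings); re-running with the same inputs is byte-reproducible.

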