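"""Patients, cohorts and the four inter-patient distance metrics.

A patient is a diagnosis-labelled set of finding concepts. Four metrics map
pairs of patients to distances in [0, 1]:

* ``jaccard`` — complement of the Jaccard similarity of the finding sets;
* ``cosine`` — cosine distance of the binarized finding vectors;
* ``augmented_cosine`` — cosine distance after each finding contributes its
  ancestor-weighted augmentation vector (near-miss findings that share
  ancestors gain partial similarity);
* ``augmented_bipartite`` — symmetrized mean-min matching under the
  Wu-Palmer concept distance: average of D(A,B) and D(B,A) where
  D(A,B) = (1/|A|) * sum over a in A of min over b in B of dist(a, b).

All metrics are symmetric, zero on the diagonal and normalized to [0, 1]
(values within 1e-12 outside the range are clipped). Duplicate findings
collapse on ingestion; severity is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ontology import Ontology, OntologyError
from .semantics import (AugmentationTable, ConceptDistanceTable, ConceptIndex)

__all__ = [
    "Patient", "Cohort", "PatientVector", "DistanceMatrix", "METRICS",
    "jaccard_distance", "binarize", "cosine_distance",
    "augment_patient_vector", "augmented_cosine_distance",
    "directed_mean_min", "augmented_bipartite_distance", "pairwise_matrix",
    "load_cohort",
]

METRICS = ("jaccard", "cosine", "augmented_cosine", "augmented_bipartite")

COHORT_COLUMNS = ("patient_id", "diagnosis", "concept_id")

_CLIP_TOL = 1e-12


@dataclass(frozen=True)
class Patient:
    """One patient: an id, a diagnosis label and a non-empty finding set."""

    id: str
    diagnosis: str
    findings: frozenset[str]

    def __post_init__(self):
        if not self.findings:
            raise ValueError(f"patient {self.id!r} has no findings")


class Cohort:
    """An ordered collection of patients tied to one ontology.

    Patient order is the input order; the concept index is the lexicographic
    index over the ontology's non-root concepts.
    """

    def __init__(self, patients: list[Patient], ontology: Ontology) -> None:
        ids = [p.id for p in patients]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dup}")
        for p in patients:
            for f in p.findings:
                if f not in ontology:
                    raise OntologyError(
                        f"patient {p.id!r}: unknown finding {f!r}")
                if f == ontology.root:
                    raise OntologyError(
                        f"patient {p.id!r}: the root is not a finding")
        self.patients = list(patients)
        self.ontology = ontology
        self.index = ConceptIndex.from_ontology(ontology)

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.patients]

    @property
    def labels(self) -> list[str]:
        return [p.diagnosis for p in self.patients]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, ontology: Ontology) -> "Cohort":
        """Build a cohort from long-format rows (one finding per row)."""
        missing = set(COHORT_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        patients = []
        for pid, grp in frame.groupby("patient_id", sort=False):
            diagnoses = grp["diagnosis"].unique()
            if len(diagnoses) > 1:
                raise ValueError(
                    f"patient {pid!r} has conflicting diagnoses: "
                    f"{sorted(diagnoses)}")
            patients.append(Patient(str(pid), str(diagnoses[0]),
                                    frozenset(grp["concept_id"].astype(str))))
        return cls(patients, ontology)

    def to_frame(self) -> pd.DataFrame:
        rows = [(p.id, p.diagnosis, f)
                for p in self.patients for f in sorted(p.findings)]
        return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def binary_matrix(self) -> np.ndarray:
        """Patients x concepts binary finding matrix."""
        return np.stack([binarize(p, self.index).values for p in self])


def load_cohort(path, ontology: Ontology) -> Cohort:
    """Load a cohort from its long-format TSV file."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return Cohort.from_frame(frame, ontology)


@dataclass(frozen=True)
class PatientVector:
    """Fixed-length non-negative vector aligned to a concept index."""

    values: np.ndarray
    kind: str  # "binary" | "augmented"


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric patient x patient distance matrix tagged by metric."""

    ids: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match patient ids")
        if not np.allclose(v, v.T, atol=_CLIP_TOL):
            raise ValueError("distance matrix is not symmetric")
        if np.any(v < -_CLIP_TOL) or np.any(v > 1 + _CLIP_TOL):
            raise ValueError("distances outside [0, 1]")

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangular (unordered pair) distances as a flat array."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(self.values, index=list(self.ids),
                             columns=list(self.ids))
        frame.to_csv(path, float_format="%.12g")

    @classmethod
    def read_csv(cls, path, metric: str = "unknown") -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(ids=tuple(str(i) for i in frame.index),
                   values=_finalize(frame.to_numpy(dtype=float)),
                   metric=metric)


def _finalize(values: np.ndarray) -> np.ndarray:
    """Symmetrize FP noise and clip to [0, 1] within tolerance."""
    v = np.asarray(values, dtype=float)
    v = (v + v.T) / 2.0
    if np.any(v < -_CLIP_TOL) or np.any(v > 1 + _CLIP_TOL):
        raise ValueError("distance outside [0, 1] beyond FP tolerance")
    np.clip(v, 0.0, 1.0, out=v)
    np.fill_diagonal(v, 0.0)
    return v


# -- pairwise metrics --------------------------------------------------------

def jaccard_distance(a: Patient, b: Patient) -> float:
    """1 - |A∩B| / |A∪B| over the two finding sets."""
    inter = len(a.findings & b.findings)
    union = len(a.findings | b.findings)
    return 1.0 - inter / union


def binarize(patient: Patient, index: ConceptIndex) -> PatientVector:
    """0/1 vector with a 1 at each finding position."""
    values = np.zeros(len(index))
    for f in patient.findings:
        values[index[f]] = 1.0
    return PatientVector(values=values, kind="binary")


def cosine_distance(u: PatientVector, v: PatientVector) -> float:
    """1 - cosine similarity; in [0, 1] because entries are non-negative."""
    nu, nv = np.linalg.norm(u.values), np.linalg.norm(v.values)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance is undefined for a zero vector")
    d = 1.0 - float(u.values @ v.values) / (nu * nv)
    return min(max(d, 0.0), 1.0)


def augment_patient_vector(patient: Patient,
                           table: AugmentationTable) -> PatientVector:
    """Sum of the augmentation vectors of the patient's findings.

    Weights from shared ancestors accumulate additively: a patient with both
    a concept and its child holds 1 + 1/2 at the concept's position.
    """
    values = np.zeros(len(table.index))
    for f in patient.findings:
        for pos, w in table[f].items():
            values[pos] += w
    return PatientVector(values=values, kind="augmented")


def augmented_cosine_distance(a: Patient, b: Patient,
                              table: AugmentationTable) -> float:
    """Cosine distance of the two semantically augmented patient vectors."""
    return cosine_distance(augment_patient_vector(a, table),
                           augment_patient_vector(b, table))


def directed_mean_min(a: Patient, b: Patient,
                      table: ConceptDistanceTable) -> float:
    """Mean over A's findings of the minimum concept distance into B."""
    sub = table.submatrix(sorted(a.findings), sorted(b.findings))
    return float(sub.min(axis=1).mean())


def augmented_bipartite_distance(a: Patient, b: Patient,
                                 table: ConceptDistanceTable) -> float:
    """Average of the two directed mean-min distances (symmetric)."""
    sub = table.submatrix(sorted(a.findings), sorted(b.findings))
    return float(sub.min(axis=1).mean() + sub.min(axis=0).mean()) / 2.0


# -- matrix construction -----------------------------------------------------

def pairwise_matrix(cohort: Cohort, metric: str,
                    distance_table: ConceptDistanceTable | None = None,
                    augmentation_table: AugmentationTable | None = None,
                    ) -> DistanceMatrix:
    """All pairwise distances for a cohort under one metric.

    Each unordered pair is computed once; the result satisfies the
    DistanceMatrix invariants (symmetry, zero diagonal, [0, 1]).
    """
    if metric not in METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; valid: {', '.join(METRICS)}")
    m = len(cohort)
    if m == 0:
        raise ValueError("empty cohort")

    if metric == "cosine":
        vecs = cohort.binary_matrix()
        values = _cosine_matrix(vecs)
    elif metric == "augmented_cosine":
        if augmentation_table is None:
            raise ValueError("augmented_cosine requires an augmentation table")
        vecs = np.stack([
            augment_patient_vector(p, augmentation_table).values
            for p in cohort])
        values = _cosine_matrix(vecs)
    elif metric == "jaccard":
        b = cohort.binary_matrix()
        inter = b @ b.T
        sizes = b.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        values = 1.0 - inter / union
    else:  # augmented_bipartite
        if distance_table is None:
            raise ValueError(
                "augmented_bipartite requires a concept distance table")
        values = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                values[i, j] = values[j, i] = augmented_bipartite_distance(
                    cohort.patients[i], cohort.patients[j], distance_table)

    return DistanceMatrix(ids=tuple(cohort.ids), values=_finalize(values),
                          metric=metric)


def _cosine_matrix(vecs: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0):
        raise ValueError("cosine distance is undefined for a zero vector")
    sim = (vecs @ vecs.T) / np.outer(norms, norms)
    return 1.0 - sim
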