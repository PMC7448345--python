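"""Model/Results front end tying the pipeline together.

``PatientSimilarityModel`` is built from a cohort and its ontology (directly,
from a long-format DataFrame, or from the TSV files); ``fit()`` derives the
semantic resources (Wu-Palmer table, augmentation table), computes the
requested distance matrices and returns a ``PatientSimilarityResults`` that
carries the matrices, their within-/between-diagnosis summaries, a
``summary()`` table, and methods running the classification/clustering
evaluation.

Typical use::

    from ontodist import SyntheticConfig, simulate, PatientSimilarityModel

    ontology, cohort = simulate(SyntheticConfig(seed=7))
    res = PatientSimilarityModel(cohort).fit()
    print(res.summary())
    scores = res.evaluate()          # tidy classifier/clusterer score frame
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats as _stats
from .evaluate import EvalConfig, evaluate_all
from .ontology import Ontology, load_ontology
from .patients import (Cohort, DistanceMatrix, METRICS, load_cohort,
                       pairwise_matrix)
from .semantics import build_augmentation_table, build_distance_table

__all__ = ["PatientSimilarityModel", "PatientSimilarityResults"]


class PatientSimilarityModel:
    """Ontology-based inter-patient distance analysis of one cohort."""

    def __init__(self, cohort: Cohort, metrics=METRICS) -> None:
        unknown = set(metrics) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        self.cohort = cohort
        self.ontology: Ontology = cohort.ontology
        self.metrics = tuple(metrics)

    @classmethod
    def from_dataframe(cls, findings: pd.DataFrame, ontology: Ontology,
                       metrics=METRICS) -> "PatientSimilarityModel":
        """Build from long-format findings (patient_id/diagnosis/concept_id)."""
        return cls(Cohort.from_frame(findings, ontology), metrics)

    @classmethod
    def from_files(cls, cohort_path, ontology_path,
                   metrics=METRICS) -> "PatientSimilarityModel":
        ontology = load_ontology(ontology_path)
        return cls(load_cohort(cohort_path, ontology), metrics)

    def fit(self) -> "PatientSimilarityResults":
        """Compute the semantic tables and all requested distance matrices."""
        needs_wp = "augmented_bipartite" in self.metrics
        needs_aug = "augmented_cosine" in self.metrics
        dist_table = build_distance_table(self.ontology) if needs_wp else None
        aug_table = (build_augmentation_table(self.ontology)
                     if needs_aug else None)
        matrices = {
            m: pairwise_matrix(self.cohort, m, distance_table=dist_table,
                               augmentation_table=aug_table)
            for m in self.metrics
        }
        return PatientSimilarityResults(self, matrices)


class PatientSimilarityResults:
    """Fitted distance matrices plus their descriptive and ML evaluation."""

    def __init__(self, model: PatientSimilarityModel,
                 matrices: dict[str, DistanceMatrix]) -> None:
        self.model = model
        self.distance_matrices = matrices
        self._labels = np.asarray(model.cohort.labels, dtype=object)

    # -- descriptive statistics ---------------------------------------------

    def within_between(self, metric: str) -> _stats.DistanceSummary:
        return _stats.within_between(self.distance_matrices[metric],
                                     self._labels)

    def metric_comparison(self) -> tuple[pd.DataFrame, _stats.FResult]:
        """Per-metric mean/SD/within/between table plus the omnibus F."""
        return _stats.metric_comparison_report(self.distance_matrices,
                                               self._labels)

    def summary(self) -> str:
        """Human-readable per-metric distance summary."""
        report, f = self.metric_comparison()
        lines = [
            "Ontology-based patient distance analysis",
            f"  patients: {len(self.model.cohort)}   "
            f"diagnoses: {len(set(self._labels))}   "
            f"concepts: {len(self.model.cohort.index)}",
            "",
            report.round(4).to_string(),
            "",
        ]
        if f.F is None:
            lines.append("one-way F across metrics: undefined "
                         f"(df = {f.df_between}, {f.df_within})")
        else:
            lines.append(f"one-way F across metrics: {f.F:.1f} "
                         f"(df = {f.df_between}, {f.df_within})")
        return "\n".join(lines)

    # -- machine-learning evaluation ----------------------------------------

    def evaluate(self, config: EvalConfig | None = None) -> pd.DataFrame:
        """Classification + clustering scores, tidy format.

        Runs all four classifiers (10-fold stratified CV) and both
        clusterers on every fitted metric's matrix.
        """
        cfg = config or EvalConfig()
        binary = (self.model.cohort.binary_matrix()
                  if cfg.features == "binary_findings" else None)
        return evaluate_all(self.distance_matrices, self._labels, cfg,
                            binary_features=binary)
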