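"""Descriptive distance statistics: within- vs between-diagnosis structure.

For each patient we compute its mean distance to other patients sharing its
diagnosis (within) and to patients with a different diagnosis (between); a
cohort in which within < between carries the signal classifiers and
clusterers exploit. An omnibus one-way F statistic across the four metrics'
pairwise-distance populations summarizes how strongly the metrics differ.

Caveat: treating each pairwise distance as an independent observation (as
the omnibus F does) ignores the dependence among pairs sharing a patient;
the F statistic is descriptive here, not a calibrated test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .patients import DistanceMatrix

__all__ = ["DistanceSummary", "FResult", "within_between", "one_way_F",
           "metric_comparison_report"]


@dataclass(frozen=True)
class FResult:
    """One-way ANOVA F statistic with its (between, within) df pair."""

    F: float | None
    df_between: int
    df_within: int


@dataclass(frozen=True)
class DistanceSummary:
    """Within/between-diagnosis distance structure of one matrix.

    ``per_patient`` holds each patient's mean within- and between-diagnosis
    distance (NaN where its diagnosis has a single member); ``per_diagnosis``
    the mean within-diagnosis distance per diagnosis, ascending.
    """

    metric: str
    mean: float
    sd: float
    per_patient: pd.DataFrame
    per_diagnosis: pd.Series
    within_mean: float
    between_mean: float


def within_between(d: DistanceMatrix, labels) -> DistanceSummary:
    """Per-patient and aggregate within-/between-diagnosis mean distances.

    Per-patient within means exclude self-distance; aggregates are
    unweighted means over the patients for which the quantity is defined.
    A single-member diagnosis yields a missing (NaN) within mean, never 0.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(d.ids):
        raise ValueError("labels not aligned with the distance matrix")
    if len(np.unique(labels)) < 2:
        raise ValueError("within/between requires >= 2 diagnoses")
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    diff = labels[:, None] != labels[None, :]
    n = len(labels)
    within = np.full(n, np.nan)
    between = np.full(n, np.nan)
    for i in range(n):
        if same[i].any():
            within[i] = d.values[i, same[i]].mean()
        if diff[i].any():
            between[i] = d.values[i, diff[i]].mean()
    per_patient = pd.DataFrame({
        "patient_id": list(d.ids), "diagnosis": labels,
        "within_mean": within, "between_mean": between,
    })
    per_diagnosis = (per_patient.groupby("diagnosis")["within_mean"]
                     .mean().sort_values())
    off = d.off_diagonal()
    return DistanceSummary(
        metric=d.metric,
        mean=float(off.mean()), sd=float(off.std(ddof=1)),
        per_patient=per_patient, per_diagnosis=per_diagnosis,
        within_mean=float(np.nanmean(within)),
        between_mean=float(np.nanmean(between)),
    )


def one_way_F(groups) -> FResult:
    """Classic one-way ANOVA F with df = (k - 1, n - k).

    When every group is the same constant (zero between- and within-group
    variance) the ratio is undefined and F is reported as missing.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    n = sum(len(g) for g in groups)
    df = (k - 1, n - k)
    grand = np.concatenate(groups)
    if np.ptp(grand) == 0:
        return FResult(F=None, df_between=df[0], df_within=df[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        f, _ = sps.f_oneway(*groups)
    return FResult(F=None if not np.isfinite(f) else float(f),
                   df_between=df[0], df_within=df[1])


def metric_comparison_report(
        matrices: dict[str, DistanceMatrix], labels,
        ) -> tuple[pd.DataFrame, FResult]:
    """Per-metric distance summary plus the omnibus F across metrics.

    Each unordered patient pair contributes one distance observation per
    metric (the symmetric matrix makes ordered pairs duplicates). Returns a
    row per metric with the off-diagonal mean/SD, within/between means and
    their gap, and the one-way F over the metrics' pairwise distances.
    """
    ids = None
    rows = []
    groups = []
    for metric, d in matrices.items():
        if ids is None:
            ids = d.ids
        elif d.ids != ids:
            raise ValueError("distance matrices are not aligned")
        s = within_between(d, labels)
        rows.append({
            "metric": metric, "mean": s.mean, "sd": s.sd,
            "within_mean": s.within_mean, "between_mean": s.between_mean,
            "gap": s.between_mean - s.within_mean,
        })
        groups.append(d.off_diagonal())
    report = pd.DataFrame(rows).set_index("metric")
    return report, one_way_F(groups)
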