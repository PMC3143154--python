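"""Double hierarchical clustering and Kaplan–Meier signature selection.

Candidate genes are mean-centered and clustered (1 − Pearson correlation,
average linkage) into gene groups; for each gene group the patients are
clustered on that group's sub-matrix, and every pair of patient groups is
compared by the two-group log-rank test on Kaplan–Meier survival. The gene
group achieving the smallest pairwise log-rank p is reported as the
signature. That minimum is a selection statistic, not a corrected p-value;
downstream output carries this caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.cluster import hierarchy

__all__ = [
    "CohortData",
    "ClusterPartition",
    "SurvivalResult",
    "mean_center",
    "cluster",
    "km_estimate",
    "logrank_test",
    "signature_scan",
    "random_signature_control",
]


@dataclass
class CohortData:
    """Patient expression matrix (genes × patients) with survival data.

    ``time`` is survival in months, ``event`` 1 for observed death and 0
    for censoring; both are indexed by patient id. Patients with missing
    survival information (NaN time) are kept in the matrix but dropped
    before any Kaplan–Meier computation. ``truth`` optionally records the
    planted structure of a synthetic cohort.
    """

    matrix: pd.DataFrame
    time: pd.Series
    event: pd.Series
    stage: pd.Series | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != list(self.time.index):
            raise ValueError("matrix columns and survival index must match")
        ev = self.event.dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")

    def complete_cases(self) -> pd.Index:
        ok = self.time.notna() & self.event.notna() & (self.time > 0)
        return self.time.index[ok]


@dataclass(frozen=True)
class ClusterPartition:
    labels: pd.Series  # item id -> group label in 1..k
    k: int
    axis: str
    linkage_method: str = "average"
    metric: str = "correlation"

    def members(self, group: int) -> list:
        return list(self.labels.index[self.labels == group])


@dataclass(frozen=True)
class SurvivalResult:
    curves: pd.DataFrame  # long format: group, time, survival, at_risk
    medians: dict
    statistic: float | None
    p_value: float | None
    group_sizes: dict


def mean_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene row's mean (log-scale input assumed)."""
    return matrix.sub(matrix.mean(axis=1), axis=0)


def cluster(
    matrix: pd.DataFrame,
    axis: str = "genes",
    k: int = 4,
    method: str = "average",
    metric: str = "correlation",
) -> ClusterPartition:
    """Agglomerative clustering with 1 − Pearson distance, average linkage.

    ``axis="genes"`` clusters rows, ``axis="patients"`` clusters columns.
    The dendrogram is cut to exactly ``k`` groups; constant items are
    rejected under the correlation metric because their distance is
    undefined (jitter or drop them first).
    """
    if axis == "patients":
        data = matrix.T
    elif axis == "genes":
        data = matrix
    else:
        raise ValueError("axis must be 'genes' or 'patients'")
    if len(data) < k:
        raise ValueError(f"cannot form {k} groups from {len(data)} items")
    values = data.to_numpy(dtype=float)
    if metric == "correlation" and np.any(values.std(axis=1) == 0):
        raise ValueError(
            "constant item under correlation distance; jitter or drop it"
        )
    Z = hierarchy.linkage(values, method=method, metric=metric)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(flat)) != k:
        raise ValueError(f"tree cut produced {len(np.unique(flat))} != {k} groups")
    return ClusterPartition(
        labels=pd.Series(flat, index=data.index),
        k=k,
        axis=axis,
        linkage_method=method,
        metric=metric,
    )


def km_estimate(
    times, events, group_labels=None
) -> SurvivalResult:
    """Kaplan–Meier product-limit curves, optionally per group.

    The median is the smallest time at which the estimated survival drops
    to ≤ 0.5 (NaN when never reached). Deaths are processed before
    censorings at tied times.
    """
    times = pd.Series(times).astype(float)
    events = pd.Series(events).astype(int).set_axis(times.index)
    if group_labels is None:
        group_labels = pd.Series(0, index=times.index)
    else:
        group_labels = pd.Series(group_labels).set_axis(times.index)
    curves = []
    medians = {}
    sizes = {}
    for g in sorted(pd.unique(group_labels)):
        mask = group_labels == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index)
        curves.append(
            pd.DataFrame(
                {
                    "group": g,
                    "time": surv.index.to_numpy(),
                    "survival": surv.to_numpy(),
                    "at_risk": at_risk.to_numpy(),
                }
            )
        )
        med = kmf.median_survival_time_
        medians[g] = float(med) if np.isfinite(med) else float("nan")
        sizes[g] = int(mask.sum())
    return SurvivalResult(
        curves=pd.concat(curves, ignore_index=True),
        medians=medians,
        statistic=None,
        p_value=None,
        group_sizes=sizes,
    )


def logrank_test(times, events, group_labels, method: str = "logrank"):
    """Two-group survival comparison.

    ``method="logrank"`` gives the standard log-rank chi-square (1 df);
    ``method="likelihood-ratio"`` gives the Cox partial-likelihood-ratio
    test on the group indicator. Returns (statistic, p).
    """
    times = pd.Series(times).astype(float).reset_index(drop=True)
    events = pd.Series(events).astype(int).reset_index(drop=True)
    groups = pd.Series(group_labels).reset_index(drop=True)
    uniq = pd.unique(groups)
    if len(uniq) != 2:
        raise ValueError("logrank_test requires exactly two groups")
    m0, m1 = groups == uniq[0], groups == uniq[1]
    if m0.sum() == 0 or m1.sum() == 0:
        raise ValueError("each group needs at least one subject")
    if method == "logrank":
        res = _ll_logrank(times[m0], times[m1], events[m0], events[m1])
        return float(res.test_statistic), float(res.p_value)
    if method == "likelihood-ratio":
        df = pd.DataFrame(
            {"time": times, "event": events, "group": (groups == uniq[1]).astype(int)}
        )
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        stat = float(cph.log_likelihood_ratio_test().test_statistic)
        p = float(cph.log_likelihood_ratio_test().p_value)
        return stat, p
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class SignatureScanResult:
    gene_partition: ClusterPartition
    per_group: pd.DataFrame  # gene_group, n_genes, best pair, best stat/p
    patient_partitions: dict
    selected_group: int | None
    note: str = (
        "best-pair log-rank p is a selection statistic over gene and "
        "patient groupings; it is not corrected for that selection"
    )

    @property
    def selected_genes(self) -> list:
        if self.selected_group is None:
            return []
        return self.gene_partition.members(self.selected_group)


def _best_pairwise_logrank(
    cohort: CohortData, patient_part: ClusterPartition
) -> tuple[tuple | None, float | None, float | None]:
    complete = cohort.complete_cases()
    labels = patient_part.labels.reindex(complete)
    best = (None, None, None)
    groups = sorted(pd.unique(labels.dropna()))
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            mask = labels.isin([a, b])
            if labels[mask].nunique() < 2:
                continue
            stat, p = logrank_test(
                cohort.time[complete][mask],
                cohort.event[complete][mask],
                labels[mask],
            )
            if best[2] is None or p < best[2]:
                best = ((int(a), int(b)), stat, p)
    return best


def signature_scan(
    cohort: CohortData,
    candidate_genes: list[str] | None = None,
    k_gene: int = 4,
    k_patient: int = 4,
) -> SignatureScanResult:
    """Double-clustering survival scan over candidate gene groups.

    Genes are clustered into ``k_gene`` groups; per gene group, patients
    are clustered into ``k_patient`` groups on that group's mean-centered
    sub-matrix, and the best pairwise log-rank p over patient groups is
    recorded. The gene group with the smallest best-pair p is selected.
    With ``k_patient=1`` there is no contrast and no test is reported.
    """
    if candidate_genes is None:
        candidate_genes = list(cohort.matrix.index)
    missing = set(candidate_genes) - set(cohort.matrix.index)
    if missing:
        raise ValueError(f"candidate genes absent from cohort: {sorted(missing)[:5]}")
    sub = mean_center(cohort.matrix.loc[list(candidate_genes)])
    gene_part = cluster(sub, axis="genes", k=k_gene)
    rows = []
    patient_parts = {}
    for g in range(1, k_gene + 1):
        members = gene_part.members(g)
        if k_patient <= 1 or len(members) < 2:
            rows.append(
                {"gene_group": g, "n_genes": len(members), "pair": None,
                 "statistic": np.nan, "p": np.nan}
            )
            continue
        patient_part = cluster(sub.loc[members], axis="patients", k=k_patient)
        patient_parts[g] = patient_part
        pair, stat, p = _best_pairwise_logrank(cohort, patient_part)
        rows.append(
            {"gene_group": g, "n_genes": len(members), "pair": pair,
             "statistic": stat, "p": p if p is not None else np.nan}
        )
    table = pd.DataFrame(rows)
    selected = None
    if table["p"].notna().any():
        selected = int(table.loc[table["p"].idxmin(), "gene_group"])
    return SignatureScanResult(
        gene_partition=gene_part,
        per_group=table,
        patient_partitions=patient_parts,
        selected_group=selected,
    )


def random_signature_control(
    cohort: CohortData,
    signature_size: int,
    excluded_genes: set[str],
    seed: int,
    k_patient: int = 4,
) -> tuple[list[str], float | None, float | None]:
    """Re-run the patient clustering + best-pair log-rank on random genes.

    Draws a size-matched gene set disjoint from ``excluded_genes`` (the
    signature) and reports the best pairwise log-rank (statistic, p) for
    comparison with the signature's. Returns (genes, statistic, p).
    """
    if signature_size <= 0:
        raise ValueError("signature_size must be positive")
    pool = [g for g in cohort.matrix.index if g not in excluded_genes]
    if len(pool) < signature_size:
        raise ValueError("not enough non-excluded genes for the control draw")
    rng = np.random.default_rng(seed)
    genes = sorted(rng.choice(pool, size=signature_size, replace=False))
    sub = mean_center(cohort.matrix.loc[genes])
    patient_part = cluster(sub, axis="patients", k=k_patient)
    _, stat, p = _best_pairwise_logrank(cohort, patient_part)
    return list(genes), stat, p
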