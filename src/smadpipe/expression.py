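"""Differential expression from triplicate arrays and target-gene overlap.

Differential expression between stimulated and unstimulated replicate
groups is called by a per-gene equal-variance two-sample t-test with a
deliberately liberal significance cut (p < 0.10) combined with a
|log2 fold change| > 0.5 requirement; no multiple-testing correction is
applied to the call (a Benjamini–Hochberg column is emitted for
information only). DE calls are then intersected with the set of genes
carrying binding loci to form a three-way partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import round_pct

__all__ = [
    "IntegrationPartition",
    "differential_expression",
    "integrate",
    "strict_variant",
]


@dataclass(frozen=True)
class IntegrationPartition:
    """Disjoint three-way split of the gene universe under study."""

    de_only: frozenset[str]
    locus_only: frozenset[str]
    de_and_locus: frozenset[str]

    def summary(self) -> dict[str, float | int]:
        n_de = len(self.de_only) + len(self.de_and_locus)
        return {
            "de_total": n_de,
            "de_only": len(self.de_only),
            "locus_only": len(self.locus_only),
            "de_and_locus": len(self.de_and_locus),
            "overlap_pct": round_pct(len(self.de_and_locus), n_de) if n_de else 0.0,
        }


def differential_expression(
    matrix: pd.DataFrame,
    group_labels: list[str] | pd.Series,
    fc_threshold: float = 0.5,
    p_threshold: float = 0.1,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Per-gene t-test and fold change between two replicate groups.

    ``matrix`` has genes as rows and samples as columns, values on log2
    scale (set ``log_transform`` for linear-scale input). ``group_labels``
    gives, per column, ``"stimulated"`` or ``"unstimulated"``. The log2
    fold change is mean(stimulated) − mean(unstimulated). Returns a frame
    indexed by gene with columns mean_stim, mean_unstim, log2fc, p, q, de.
    """
    labels = pd.Series(list(group_labels), index=matrix.columns)
    stim_cols = labels.index[labels == "stimulated"]
    unstim_cols = labels.index[labels == "unstimulated"]
    if len(stim_cols) < 2 or len(unstim_cols) < 2:
        raise ValueError("each condition needs at least 2 replicates")
    values = matrix.to_numpy(dtype=float)
    if log_transform:
        values = np.log2(values)
    stim = values[:, matrix.columns.get_indexer(stim_cols)]
    unstim = values[:, matrix.columns.get_indexer(unstim_cols)]

    mean_s = stim.mean(axis=1)
    mean_u = unstim.mean(axis=1)
    log2fc = mean_s - mean_u
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(stim, unstim, axis=1, equal_var=True)
    # zero within-group variance in both groups: p=1 if the means agree,
    # else the difference is exact and p -> 0
    degenerate = np.isnan(p)
    p = np.where(degenerate & (mean_s == mean_u), 1.0, p)
    p = np.where(degenerate & (mean_s != mean_u), 0.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    de = (np.abs(log2fc) > fc_threshold) & (p < p_threshold)
    return pd.DataFrame(
        {
            "mean_stim": mean_s,
            "mean_unstim": mean_u,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "de": de,
        },
        index=matrix.index.rename("gene_id"),
    )


def integrate(
    results: pd.DataFrame, target_gene_ids: set[str]
) -> IntegrationPartition:
    """Partition genes by DE flag × binding-locus membership."""
    de_genes = set(results.index[results["de"]])
    targets = set(target_gene_ids)
    return IntegrationPartition(
        de_only=frozenset(de_genes - targets),
        locus_only=frozenset((targets & set(results.index)) - de_genes),
        de_and_locus=frozenset(de_genes & targets),
    )


def strict_variant(
    results: pd.DataFrame,
    target_gene_ids: set[str],
    p_threshold: float = 0.05,
    fc_threshold: float = 0.5,
) -> IntegrationPartition:
    """Re-call DE at a stricter p threshold and re-partition."""
    strict = results.copy()
    strict["de"] = (strict["log2fc"].abs() > fc_threshold) & (
        strict["p"] < p_threshold
    )
    return integrate(strict, target_gene_ids)
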