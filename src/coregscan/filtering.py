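"""Frequent-alteration filtering, tumor clustering and cross-cohort intersection.

The filter keeps genes altered beyond a Z threshold in at least a given
fraction of tumors (strict inequality on Z, non-strict on the fraction).
Two shipped presets reflect the two thresholds used in practice for this
kind of screen: ``text-2.0`` (|Z| > 2 in 35% of tumors) and ``figure-2.5``
(|Z| > 2.5 in 35%).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "FilterSpec",
    "FILTER_PRESETS",
    "frequent_alteration_filter",
    "cluster_tumors",
    "cluster_outcome_association",
    "ClusterAssociation",
    "categorize_at_median",
    "intersect_cohorts",
    "IntersectionReport",
]


@dataclass(frozen=True)
class FilterSpec:
    """Keep genes with |Z| (or signed Z) > t in at least fraction f of tumors."""

    z_threshold: float = 2.5
    tumor_fraction: float = 0.35
    direction: str = "either"

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if not (0 < self.tumor_fraction <= 1):
            raise ValueError("tumor_fraction must be in (0, 1]")
        if self.direction not in ("up", "down", "either"):
            raise ValueError("direction must be 'up', 'down' or 'either'")


FILTER_PRESETS: dict[str, FilterSpec] = {
    "text-2.0": FilterSpec(z_threshold=2.0, tumor_fraction=0.35, direction="either"),
    "figure-2.5": FilterSpec(z_threshold=2.5, tumor_fraction=0.35, direction="either"),
}


def frequent_alteration_filter(z: pd.DataFrame, spec: FilterSpec) -> list[str]:
    """Genes altered by > t Z-scores in >= f of tumors, per the spec's direction."""
    if z.empty:
        raise ValueError("Z-score matrix is empty")
    if spec.direction == "down":
        hits = z < -spec.z_threshold
    elif spec.direction == "up":
        hits = z > spec.z_threshold
    else:
        hits = z.abs() > spec.z_threshold
    frac = hits.mean(axis=1)
    return frac.index[frac >= spec.tumor_fraction].tolist()


def cluster_tumors(
    z_subset: pd.DataFrame,
    k: int = 2,
    method: str = "complete",
    metric: str = "euclidean",
) -> pd.Series:
    """Hierarchical clustering of tumors (columns) cut at k clusters.

    Complete linkage on Euclidean distance by default, mirroring the usual
    clustered-heatmap defaults. Returns integer labels (1..k) indexed by
    tumor.
    """
    n_tumors = z_subset.shape[1]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_tumors:
        raise ValueError(f"cannot cut {n_tumors} tumors into {k} clusters")
    link = linkage(z_subset.to_numpy().T, method=method, metric=metric)
    labels = fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=z_subset.columns, name="cluster")


@dataclass
class ClusterAssociation:
    """Chi-squared association between cluster membership and a clinical category."""

    table: pd.DataFrame
    chi_squared: float
    df: int
    p: float

    def report(self) -> str:
        return f"X-squared = {self.chi_squared:.4f}, p-value = {self.p:.3g}"


def cluster_outcome_association(
    labels: pd.Series, clinical_category: pd.Series
) -> ClusterAssociation:
    """Pearson chi-squared (no continuity correction) on cluster x category."""
    joined = pd.concat(
        [labels.rename("cluster"), clinical_category.rename("category")], axis=1
    ).dropna()
    table = pd.crosstab(joined["cluster"], joined["category"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 clusters and >= 2 categories with non-zero margins")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty margin")
    chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return ClusterAssociation(table=table, chi_squared=float(chi2), df=int(df), p=float(p))


def categorize_at_median(values: pd.Series, labels: tuple[str, str] = ("low", "high")) -> pd.Series:
    """Dichotomize a continuous clinical variable at its median (<= vs >)."""
    med = values.median()
    return pd.Series(
        np.where(values <= med, labels[0], labels[1]), index=values.index, name=values.name
    )


@dataclass
class IntersectionReport:
    """Cross-cohort gene-list intersection (UpSet-style exclusive combinations)."""

    membership: pd.DataFrame  # genes x cohorts boolean
    combination_sizes: dict[tuple[str, ...], int]

    @property
    def union_size(self) -> int:
        return len(self.membership)

    def size_of(self, *cohorts: str) -> int:
        return self.combination_sizes.get(tuple(sorted(cohorts)), 0)


def intersect_cohorts(gene_lists: Mapping[str, Sequence[str]]) -> IntersectionReport:
    """Exclusive-combination sizes across >= 2 cohort gene lists.

    Each gene in the union is assigned to exactly one combination (the set
    of cohorts containing it), so combination sizes sum to the union size.
    """
    if len(gene_lists) < 2:
        raise ValueError("need gene lists from at least 2 cohorts")
    cohorts = sorted(gene_lists)
    union = sorted(set().union(*(set(g) for g in gene_lists.values())))
    membership = pd.DataFrame(
        {c: [g in set(gene_lists[c]) for g in union] for c in cohorts}, index=union
    )
    sizes: dict[tuple[str, ...], int] = {}
    for r in range(1, len(cohorts) + 1):
        for combo in combinations(cohorts, r):
            in_combo = membership[list(combo)].all(axis=1)
            out_combo = (
                ~membership[[c for c in cohorts if c not in combo]].any(axis=1)
                if len(combo) < len(cohorts)
                else pd.Series(True, index=membership.index)
            )
            n = int((in_combo & out_combo).sum())
            if n:
                sizes[tuple(combo)] = n
    return IntersectionReport(membership=membership, combination_sizes=sizes)
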