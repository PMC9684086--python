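"""Dominance-based community typing and the associated group statistics.

A sample's community type is the species reaching at least half of its
composition; samples without such a species form the "diverse" type. Group
comparisons use a Gaussian likelihood-ratio test with pooled-variance t post
hocs, Wilcoxon rank-sum tests, and Fisher exact co-occurrence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage

from crowdome.io import AbundanceTable
from crowdome.stats import FisherResult, fisher_cooccurrence

logger = logging.getLogger(__name__)

DIVERSE = "diverse"

__all__ = [
    "DIVERSE",
    "TypeAssignment",
    "TypeTestResult",
    "assign_types",
    "cluster_order",
    "type_covariate_test",
    "fisher_cooccurrence",
    "FisherResult",
    "ranksum_compare",
]


@dataclass
class TypeAssignment:
    """Per-sample community-type labels and the dominant species' share."""

    labels: pd.Series
    dominant_fraction: pd.Series
    threshold: float = 0.5

    def counts(self) -> pd.Series:
        return self.labels.value_counts()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"community_type": self.labels, "dominant_fraction": self.dominant_fraction}
        )


@dataclass
class TypeTestResult:
    """Overall LR-test P plus pairwise pooled-t post hoc P values."""

    covariate: str
    overall_p: float
    pairwise: pd.DataFrame
    group_ns: pd.Series
    n_used: int
    excluded_groups: list = field(default_factory=list)


def assign_types(table: AbundanceTable, threshold: float = 0.5) -> TypeAssignment:
    """Assign each sample the community type of its dominant species.

    A sample whose maximum species fraction reaches ``threshold`` is labeled
    with that species; otherwise it is "diverse". Ties at the maximum are
    broken lexicographically. All-zero samples become "diverse" with a
    warning.
    """
    data = table.data
    if data.empty:
        raise ValueError("empty abundance table")
    values = data.to_numpy(dtype=float)
    # lexicographic tie-break: scan columns in sorted order, keep first argmax
    col_order = np.argsort(np.asarray(data.columns, dtype=object), kind="mergesort")
    ordered = values[:, col_order]
    best = ordered.argmax(axis=1)
    frac = ordered[np.arange(len(data)), best]
    names = np.asarray(data.columns, dtype=object)[col_order]

    labels = np.where(frac >= threshold, names[best], DIVERSE)
    zero = frac <= 0
    if zero.any():
        logger.warning("%d all-zero samples labeled %s", int(zero.sum()), DIVERSE)
        labels = np.where(zero, DIVERSE, labels)
    return TypeAssignment(
        pd.Series(labels, index=data.index, name="community_type"),
        pd.Series(frac, index=data.index, name="dominant_fraction"),
        threshold,
    )


def cluster_order(table: AbundanceTable):
    """Leaf order of centroid-linkage clustering on Euclidean distances.

    Returns ``(ordered_sample_ids, linkage_matrix)``; a single sample yields
    the identity order with an empty linkage.
    """
    data = table.data
    if len(data) < 2:
        return list(data.index), np.empty((0, 4))
    Z = linkage(data.to_numpy(dtype=float), method="centroid", metric="euclidean")
    order = leaves_list(Z)
    return [data.index[i] for i in order], Z


def _gaussian_lr_p(groups: list[np.ndarray]) -> float:
    """LR test of {value ~ group} vs intercept-only under Gaussian errors.

    Statistic 2*delta-loglik = n*log(SS0/SS1), chi-square with k-1 df.
    """
    all_vals = np.concatenate(groups)
    n = all_vals.size
    ss0 = float(((all_vals - all_vals.mean()) ** 2).sum())
    ss1 = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    if ss0 <= 0:
        return 1.0
    if ss1 <= 0:
        return 0.0
    stat = n * np.log(ss0 / ss1)
    return float(sps.chi2.sf(stat, df=len(groups) - 1))


def type_covariate_test(
    assignment: TypeAssignment,
    covariate: pd.Series,
    min_group: int = 3,
    name: str | None = None,
) -> TypeTestResult:
    """Test a covariate for differences among community types.

    Missing covariate values are dropped; groups smaller than ``min_group``
    are excluded (logged). The overall P comes from a Gaussian
    likelihood-ratio test, the post hocs from pooled-variance two-sample
    t-tests over all retained group pairs.
    """
    cov = pd.Series(covariate).reindex(assignment.labels.index).astype(float)
    keep = cov.notna()
    labels = assignment.labels[keep]
    cov = cov[keep]

    sizes = labels.value_counts()
    excluded = sorted(sizes.index[sizes < min_group])
    if excluded:
        logger.info("excluding groups below min_group=%d: %s", min_group, excluded)
    kept = [g for g in sizes.index if g not in excluded]
    if len(kept) < 2:
        raise ValueError("need at least 2 groups with min_group members")
    groups = {g: cov[labels == g].to_numpy(dtype=float) for g in kept}

    if np.ptp(cov[labels.isin(kept)].to_numpy(dtype=float)) == 0:
        overall_p = 1.0
    else:
        overall_p = _gaussian_lr_p(list(groups.values()))

    kept_sorted = sorted(kept)
    pair = pd.DataFrame(np.nan, index=kept_sorted, columns=kept_sorted)
    for g1, g2 in itertools.combinations(kept_sorted, 2):
        x, y = groups[g1], groups[g2]
        if np.ptp(np.concatenate([x, y])) == 0:
            p = 1.0
        else:
            p = float(sps.ttest_ind(x, y, equal_var=True).pvalue)
        pair.loc[g1, g2] = pair.loc[g2, g1] = p
    np.fill_diagonal(pair.values, 1.0)

    return TypeTestResult(
        covariate=name or (covariate.name if hasattr(covariate, "name") else "covariate"),
        overall_p=overall_p,
        pairwise=pair,
        group_ns=pd.Series({g: len(groups[g]) for g in kept_sorted}),
        n_used=int(sum(len(v) for v in groups.values())),
        excluded_groups=excluded,
    )


def ranksum_compare(x, y) -> float:
    """Two-sided Wilcoxon rank-sum P between two groups.

    Exact enumeration when both groups have at most 10 observations and no
    cross-group ties; otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return 1.0
    ties = len(np.unique(combined)) < combined.size
    if x.size <= 10 and y.size <= 10 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    # a dead-center U (e.g. identical groups) is P = 1 regardless of the
    # continuity correction's direction
    if float(res.statistic) == x.size * y.size / 2:
        return 1.0
    return float(min(res.pvalue, 1.0))
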