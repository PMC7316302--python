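"""Sample clustering on high-variance superenhancers and group comparisons.

The workflow: select the top fraction of consensus SEs by variance of SE
size, compute sample-sample Pearson correlation of their log scores, cluster
with average linkage (UPGMA) on 1 - r distance, cut the tree at a chosen k,
dissolve clusters smaller than ``min_cluster_size`` into "unassigned", and
identify the SEs whose activity stratifies the resulting groups. The same
machinery applies unchanged to an expression matrix for RNA-based
clustering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusterAssignment",
    "top_variable",
    "correlate_samples",
    "hierarchical_cluster",
    "cluster_diagnostics",
    "assign_group_specific",
    "compare_groups",
]


@dataclass
class ClusterAssignment:
    """Sample -> cluster label (None = unassigned) plus the linkage tree."""

    labels: dict[str, int | None]
    linkage: np.ndarray
    chosen_k: int
    sample_ids: list[str]
    diagnostics: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def assigned(self) -> dict[str, int]:
        return {s: c for s, c in self.labels.items() if c is not None}

    def members(self, label: int) -> list[str]:
        return [s for s, c in self.labels.items() if c == label]

    @property
    def cluster_labels(self) -> list[int]:
        return sorted({c for c in self.labels.values() if c is not None})


def top_variable(
    sizes: pd.DataFrame,
    fraction: float = 0.10,
    restrict_to: list[str] | None = None,
) -> list[str]:
    """Top ``fraction`` of features by variance of SE size (ceiling count).

    Variance is computed across ``restrict_to`` samples (default: all
    columns); ties are broken by feature id so selection is order-invariant.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    cols = list(sizes.columns) if restrict_to is None else list(restrict_to)
    if len(cols) < 2:
        raise ValueError("need >= 2 samples to compute variance")
    variances = sizes[cols].var(axis=1, ddof=1)
    n_keep = math.ceil(fraction * len(sizes))
    order = sorted(sizes.index, key=lambda fid: (-variances[fid], fid))
    return order[:n_keep]


def correlate_samples(log_scores: pd.DataFrame) -> pd.DataFrame:
    """Symmetric sample x sample Pearson matrix on log scores.

    Zero-variance samples cannot be correlated; they are dropped with a
    warning (and are therefore excluded from clustering).
    """
    if len(log_scores) < 2:
        raise ValueError("need >= 2 features to correlate samples")
    variances = log_scores.var(axis=0, ddof=0)
    flat = [s for s in log_scores.columns if variances[s] == 0]
    if flat:
        warnings.warn(f"dropping zero-variance samples from correlation: {flat}")
    kept = [s for s in log_scores.columns if s not in set(flat)]
    corr = np.corrcoef(log_scores[kept].to_numpy().T)
    corr = pd.DataFrame(corr, index=kept, columns=kept)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def hierarchical_cluster(
    corr: pd.DataFrame,
    k: int,
    min_cluster_size: int = 3,
    diagnostics_range: range | None = None,
) -> ClusterAssignment:
    """Average-linkage (UPGMA) clustering on distance = 1 - Pearson r.

    The tree is cut at ``k`` groups; groups with fewer than
    ``min_cluster_size`` members are dissolved and their samples left
    unassigned. Diagnostic curves (elbow / silhouette) are reported for a
    range of k but never override the chosen k.
    """
    sample_ids = sorted(corr.columns)
    if k > len(sample_ids):
        raise ValueError(f"k={k} exceeds number of samples ({len(sample_ids)})")
    corr = corr.loc[sample_ids, sample_ids]
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    condensed = squareform((dist + dist.T) / 2.0, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    counts = pd.Series(flat).value_counts()
    labels: dict[str, int | None] = {}
    for sample, cl in zip(sample_ids, flat):
        labels[sample] = int(cl) if counts[cl] >= min_cluster_size else None
    diag = None
    if diagnostics_range is not None:
        diag = cluster_diagnostics(corr, diagnostics_range)
    return ClusterAssignment(
        labels=labels,
        linkage=linkage,
        chosen_k=k,
        sample_ids=sample_ids,
        diagnostics=diag,
    )


def cluster_diagnostics(corr: pd.DataFrame, k_range: range) -> pd.DataFrame:
    """Elbow (within-cluster dispersion) and silhouette curves over k."""
    sample_ids = list(corr.columns)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    rows = []
    for k in k_range:
        if k < 2 or k >= len(sample_ids):
            continue
        flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        within = 0.0
        for cl in np.unique(flat):
            members = np.where(flat == cl)[0]
            if len(members) > 1:
                sub = dist[np.ix_(members, members)]
                within += sub.sum() / (2 * len(members))
        sil = silhouette_score(dist, flat, metric="precomputed") if len(np.unique(flat)) > 1 else np.nan
        rows.append({"k": k, "within_dispersion": within, "silhouette": sil})
    return pd.DataFrame(rows)


def assign_group_specific(
    log_scores: pd.DataFrame,
    assignment: ClusterAssignment,
    strict: bool = True,
) -> pd.DataFrame:
    """SEs whose activity stratifies the assigned clusters.

    For each element, find the maximal set S of clusters such that for every
    group g in S and every group h outside S, mean_g - sd_g > mean_h (the
    "mean minus SD does not overlap the other groups' means" criterion; SD is
    the sample SD). A singleton S marks a cluster-specific SE; a larger
    proper subset marks an SE shared among those clusters. Valid S are always
    top runs of the clusters ordered by mean, so only prefixes are tested.
    """
    groups = {
        label: assignment.members(label) for label in assignment.cluster_labels
    }
    usable = {}
    for label, members in groups.items():
        if len(members) < 2:
            warnings.warn(f"cluster {label} has < 2 members; SD undefined, skipping")
            continue
        usable[label] = members
    if len(usable) < 2:
        raise ValueError("need >= 2 clusters with >= 2 members")
    cmp = (lambda a, b: a > b) if strict else (lambda a, b: a >= b)
    rows = []
    for element in log_scores.index:
        means = {g: float(log_scores.loc[element, m].mean()) for g, m in usable.items()}
        sds = {g: float(log_scores.loc[element, m].std(ddof=1)) for g, m in usable.items()}
        ordered = sorted(usable, key=lambda g: (-means[g], g))
        chosen: tuple[int, ...] | None = None
        for m in range(len(ordered) - 1, 0, -1):
            inside, outside = ordered[:m], ordered[m:]
            lo = min(means[g] - sds[g] for g in inside)
            hi = max(means[h] for h in outside)
            if cmp(lo, hi):
                chosen = tuple(sorted(inside))
                break
        record = {
            "element": element,
            "specific_to": ",".join(map(str, chosen)) if chosen else "",
            "n_groups": len(chosen) if chosen else 0,
        }
        for g in usable:
            record[f"mean_{g}"] = means[g]
            record[f"sd_{g}"] = sds[g]
        rows.append(record)
    return pd.DataFrame(rows).set_index("element")


def compare_groups(
    group1: np.ndarray,
    group2: np.ndarray,
    test: str = "t",
) -> tuple[float, float]:
    """Two-sided unpaired comparison of two sample groups.

    ``test="t"`` is the classic pooled-variance unpaired t-test;
    ``test="mannwhitney"`` is the Mann-Whitney U test.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if test == "t":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-test needs n >= 2 per group")
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError("zero variance in both groups; t-test undefined")
        stat, p = stats.ttest_ind(a, b, equal_var=True)
    elif test == "mannwhitney":
        if len(a) < 1 or len(b) < 1:
            raise ValueError("U test needs n >= 1 per group")
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(stat), float(p)
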