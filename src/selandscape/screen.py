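"""CRISPR dropout-screen scoring and dependency-correlated SE signatures.

Per-guide log2 fold-changes between the screen start (t0) and the late
timepoint are summarized per gene as the mean of the most-depleted
``top_guides`` guides, then mapped onto a control-anchored scale where the
mean of the positive-control (essential) genes is -1.0 and the mean of the
non-targeting-control (NTC) genes is 0.0. Genes at or below -0.5 on that
scale are putative hits. Dependency labels from a CERES-like score table
feed a signature of the SEs most positively and most negatively correlated
with dependency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import compare_groups

__all__ = [
    "guide_lfc",
    "gene_lfc",
    "normalize_lfc",
    "call_hits",
    "score_screen",
    "classify_dependent",
    "DependencySignature",
    "dependency_signature",
    "permutation_separation_p",
    "sweep_signature_size",
]


def guide_lfc(
    counts_t0: pd.Series,
    counts_late: pd.Series,
    pseudocount: float = 0.5,
    t0_library: float | None = None,
    late_library: float | None = None,
) -> pd.Series:
    """Per-guide LFC = log2((late CPM + p) / (t0 CPM + p)).

    Counts are library-size normalized to counts-per-million before the
    pseudocount; libraries default to the column totals. Guides missing at
    either timepoint are excluded with a warning.
    """
    shared = counts_t0.index.intersection(counts_late.index)
    missing = counts_t0.index.symmetric_difference(counts_late.index)
    if len(missing):
        warnings.warn(f"excluding {len(missing)} guides missing at one timepoint")
    t0 = counts_t0.loc[shared].astype(float)
    late = counts_late.loc[shared].astype(float)
    t0_library = float(t0.sum()) if t0_library is None else float(t0_library)
    late_library = float(late.sum()) if late_library is None else float(late_library)
    if t0_library <= 0 or late_library <= 0:
        raise ValueError("library sizes must be positive")
    cpm_t0 = t0 / t0_library * 1e6
    cpm_late = late / late_library * 1e6
    return np.log2((cpm_late + pseudocount) / (cpm_t0 + pseudocount))


def gene_lfc(guide_lfcs: np.ndarray | pd.Series, top_guides: int = 3) -> float:
    """Mean of the ``top_guides`` most-depleted (most negative) guide LFCs.

    Uses all guides when fewer than ``top_guides`` are available.
    """
    values = np.sort(np.asarray(guide_lfcs, dtype=float))
    if values.size == 0:
        raise ValueError("gene has no guide LFCs")
    return float(values[: min(top_guides, values.size)].mean())


def normalize_lfc(
    raw_lfcs: pd.Series,
    positive_control_genes: list[str],
    ntc_genes: list[str],
) -> pd.Series:
    """Affine map putting essential-gene mean at -1.0 and NTC mean at 0.0.

    norm(x) = -(x - m_NTC) / (m_pos - m_NTC). Invariant to any affine
    transform of all raw LFCs (the anchors move with the data); a screen
    where the controls do not separate fails QC and raises.
    """
    pos = [g for g in positive_control_genes if g in raw_lfcs.index]
    ntc = [g for g in ntc_genes if g in raw_lfcs.index]
    if not pos or not ntc:
        raise ValueError("both control gene sets must be non-empty and scored")
    m_pos = float(raw_lfcs.loc[pos].mean())
    m_ntc = float(raw_lfcs.loc[ntc].mean())
    if m_pos == m_ntc:
        raise ValueError("positive-control and NTC means coincide; screen failed QC")
    return -(raw_lfcs - m_ntc) / (m_pos - m_ntc)


def call_hits(norm_lfcs: pd.Series, hit_cutoff: float = -0.5) -> pd.Series:
    """Hit flag per gene: normalized LFC at or below the cutoff (inclusive)."""
    return norm_lfcs <= hit_cutoff


def score_screen(
    counts: pd.DataFrame,
    roles: pd.Series,
    top_guides: int = 3,
    hit_cutoff: float = -0.5,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Full screen scoring for one cell line.

    ``counts`` columns: guide, gene, count_t0, count_late. ``roles`` maps
    gene -> {target, positive_control, NTC}. Returns a gene-level table with
    raw_lfc, norm_lfc, is_hit and role.
    """
    required = {"guide", "gene", "count_t0", "count_late"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    lfcs = guide_lfc(
        counts.set_index("guide")["count_t0"],
        counts.set_index("guide")["count_late"],
        pseudocount=pseudocount,
    )
    gene_of = counts.set_index("guide")["gene"]
    raw = lfcs.groupby(gene_of).apply(lambda v: gene_lfc(v, top_guides=top_guides))
    pos = [g for g in raw.index if roles.get(g) == "positive_control"]
    ntc = [g for g in raw.index if roles.get(g) == "NTC"]
    norm = normalize_lfc(raw, pos, ntc)
    result = pd.DataFrame(
        {
            "raw_lfc": raw,
            "norm_lfc": norm,
            "is_hit": call_hits(norm, hit_cutoff),
            "role": [roles.get(g, "target") for g in raw.index],
            "n_guides": counts.groupby("gene")["guide"].count().reindex(raw.index),
        }
    )
    result.index.name = "gene"
    return result


def classify_dependent(
    ceres_scores: pd.Series, ceres_cutoff: float = -0.5
) -> pd.Series:
    """Sensitive iff the CERES-like dependency score is <= the cutoff.

    Lines with missing scores are left unlabeled (dropped).
    """
    scores = ceres_scores.dropna()
    return scores <= ceres_cutoff


@dataclass
class DependencySignature:
    """Top positively / negatively dependency-correlated SEs.

    ``separation_p`` is the two-sided p-value distinguishing dependent from
    independent lines by their per-line summed signature score (positive-set
    sum minus negative-set sum of log scores).
    """

    positive: pd.Series  # element -> r, descending
    negative: pd.Series  # element -> r, ascending
    signature_size: int
    per_line_score: pd.Series
    separation_p: float


def _dependency_correlations(log_scores: pd.DataFrame, labels: pd.Series) -> pd.Series:
    lines = [s for s in log_scores.columns if s in labels.index]
    y = labels.loc[lines].astype(float).to_numpy()
    if y.std() == 0:
        raise ValueError("need both dependent and independent lines")
    mat = log_scores[lines].to_numpy()
    sd = mat.std(axis=1)
    yc = (y - y.mean()) / y.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = ((mat - mat.mean(axis=1, keepdims=True)) * yc).mean(axis=1) / sd
    r = np.where(sd == 0, 0.0, r)  # constant elements carry no information
    return pd.Series(r, index=log_scores.index)


def dependency_signature(
    log_scores: pd.DataFrame,
    labels: pd.Series,
    signature_size: int = 600,
    test: str = "mannwhitney",
) -> DependencySignature:
    """Point-biserial correlation of each SE's log score with dependency.

    The ``signature_size`` most positively and most negatively correlated
    SEs (all available when fewer) form the signature; the separation
    p-value compares the per-line summed signature scores of dependent vs
    independent lines.
    """
    lines = [s for s in log_scores.columns if s in labels.index]
    if min(labels.loc[lines].sum(), (~labels.loc[lines]).sum()) < 2:
        raise ValueError("need >= 2 lines per dependency class")
    r = _dependency_correlations(log_scores, labels).sort_values(
        ascending=False, kind="stable"
    )
    size = min(signature_size, len(r) // 2)
    positive = r.iloc[:size]
    negative = r.iloc[::-1].iloc[:size]
    score = (
        log_scores.loc[positive.index, lines].sum(axis=0)
        - log_scores.loc[negative.index, lines].sum(axis=0)
    )
    dep = score[labels.loc[lines].to_numpy()]
    indep = score[~labels.loc[lines].to_numpy()]
    _, p = compare_groups(dep.to_numpy(), indep.to_numpy(), test=test)
    return DependencySignature(
        positive=positive,
        negative=negative,
        signature_size=size,
        per_line_score=score,
        separation_p=p,
    )


def permutation_separation_p(
    log_scores: pd.DataFrame,
    labels: pd.Series,
    signature_size: int = 600,
    n_permutations: int = 199,
    seed: int = 0,
) -> float:
    """Permutation-calibrated separation p-value.

    The naive ``separation_p`` is optimistically biased because the
    signature is selected on the same labels it is then tested against
    (selection circularity). Here the whole procedure — selection plus
    separation statistic — is re-run on label permutations, and the
    empirical p is the fraction of permutations separating at least as
    well; this is uniform under the null.
    """
    rng = np.random.default_rng(seed)
    lines = [s for s in log_scores.columns if s in labels.index]
    y = labels.loc[lines].to_numpy()

    def stat(lab: pd.Series) -> float:
        sig = dependency_signature(log_scores, lab, signature_size=signature_size)
        dep = sig.per_line_score[lab.loc[lines].to_numpy()]
        indep = sig.per_line_score[~lab.loc[lines].to_numpy()]
        return float(dep.mean() - indep.mean())

    observed = stat(labels)
    hits = 0
    for _ in range(n_permutations):
        perm = pd.Series(rng.permutation(y), index=lines)
        if stat(perm) >= observed:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


def sweep_signature_size(
    log_scores: pd.DataFrame,
    labels: pd.Series,
    sizes: list[int],
    test: str = "mannwhitney",
) -> pd.DataFrame:
    """Separation p-value over candidate signature sizes."""
    rows = []
    for size in sizes:
        sig = dependency_signature(log_scores, labels, signature_size=size, test=test)
        rows.append({"signature_size": sig.signature_size, "separation_p": sig.separation_p})
    return pd.DataFrame(rows)
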