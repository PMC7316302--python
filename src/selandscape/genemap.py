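"""Associate consensus superenhancers with putative target genes.

For each SE, every gene whose span lies within ``gene_window`` (10 Mb) is a
candidate; the Pearson correlation between log2(SE size + 1) and
log2(gene RPKM + 1) across cell-line samples decides association. Genes at
r >= 0.6 are associated; every SE additionally receives its
``min_genes`` highest-correlated candidates regardless of the threshold
(mandatory associations).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = ["genes_in_window", "pearson_log", "associate", "associate_all", "distance_report"]


def _interval_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    return a.gap(b)


def genes_in_window(
    element: GenomicInterval,
    genes: pd.DataFrame,
    window: int = 10_000_000,
) -> pd.DataFrame:
    """Candidate genes within ``window`` bp of the element (inclusive).

    ``genes`` columns: gene_id, chrom, start, end (gene spans, 0-based
    half-open). Distance is 0 for overlapping genes, else the nearest-edge
    gap. The boundary is inclusive: a gene edge exactly ``window`` bp away
    is a candidate.
    """
    same = genes[genes["chrom"] == element.chrom]
    if same.empty:
        return same.assign(distance_bp=pd.Series(dtype=int))
    gap = np.maximum(
        0,
        np.maximum(
            same["start"].to_numpy() - element.end,
            element.start - same["end"].to_numpy(),
        ),
    )
    hit = gap <= window
    out = same.loc[hit].copy()
    out["distance_bp"] = gap[hit]
    return out


def pearson_log(size: np.ndarray, expression: np.ndarray) -> float:
    """Pearson r between log2(size+1) and log2(RPKM+1); 0 if either is flat.

    A zero-variance vector has no defined correlation; defining r = 0 keeps
    batch runs alive (such genes stay eligible for mandatory slots only).
    """
    x = np.log2(np.asarray(size, dtype=float) + 1.0)
    y = np.log2(np.asarray(expression, dtype=float) + 1.0)
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def associate(
    element_id: str,
    element_size: pd.Series,
    candidates: pd.DataFrame,
    expression: pd.DataFrame,
    samples: Sequence[str],
    corr_threshold: float = 0.6,
    min_genes: int = 2,
) -> pd.DataFrame:
    """Associations for one SE: threshold passers plus mandatory top genes.

    ``element_size`` is the per-sample SE size; ``expression`` is gene x
    sample RPKM; ``samples`` selects the columns to correlate over (the
    cell lines). Output is sorted by r descending, ties by distance then
    gene id. ``mandatory`` marks genes included only through the
    minimum-``min_genes`` rule.
    """
    if len(samples) < 3:
        raise ValueError("need >= 3 samples to correlate")
    size = element_size.loc[list(samples)].to_numpy()
    rows = []
    for rec in candidates.itertuples():
        gene = rec.gene_id
        if gene not in expression.index:
            continue
        r = pearson_log(size, expression.loc[gene, list(samples)].to_numpy())
        rows.append({"gene": gene, "r": r, "distance_bp": int(rec.distance_bp)})
    table = pd.DataFrame(rows, columns=["gene", "r", "distance_bp"])
    flagged = len(table) < min_genes
    if flagged:
        warnings.warn(
            f"{element_id}: only {len(table)} candidate genes in window "
            f"(minimum {min_genes}); returning all"
        )
    table = table.sort_values(
        ["r", "distance_bp", "gene"], ascending=[False, True, True]
    ).reset_index(drop=True)
    passing = table["r"] >= corr_threshold
    mandatory_slots = table.index < min_genes
    keep = passing | mandatory_slots
    out = table.loc[keep].copy()
    out.insert(0, "element", element_id)
    out["mandatory"] = ~passing.loc[keep]
    out["flagged"] = flagged
    return out.reset_index(drop=True)


def associate_all(
    sizes: pd.DataFrame,
    element_intervals: dict[str, GenomicInterval],
    genes: pd.DataFrame,
    expression: pd.DataFrame,
    samples: Sequence[str],
    window: int = 10_000_000,
    corr_threshold: float = 0.6,
    min_genes: int = 2,
) -> pd.DataFrame:
    """Run the window + correlation association for every element in ``sizes``."""
    pieces = []
    for element_id in sizes.index:
        interval = element_intervals[element_id]
        candidates = genes_in_window(interval, genes, window)
        if candidates.empty:
            warnings.warn(f"{element_id}: no genes within window")
            continue
        pieces.append(
            associate(
                element_id,
                sizes.loc[element_id],
                candidates,
                expression,
                samples,
                corr_threshold=corr_threshold,
                min_genes=min_genes,
            )
        )
    if not pieces:
        return pd.DataFrame(
            columns=["element", "gene", "r", "distance_bp", "mandatory", "flagged"]
        )
    return pd.concat(pieces, ignore_index=True)


def distance_report(associations: pd.DataFrame) -> dict:
    """Distribution of SE-gene distances over an association table."""
    distances = associations["distance_bp"].to_numpy()
    quantiles = {}
    if len(distances):
        qs = np.quantile(distances, [0.0, 0.25, 0.5, 0.75, 1.0])
        quantiles = dict(zip(["min", "q25", "median", "q75", "max"], map(float, qs)))
    return {
        "n": int(len(distances)),
        "distances": distances.tolist(),
        "quantiles": quantiles,
    }
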