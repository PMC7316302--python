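"""Tumor-specific superenhancer calling.

An SE is tumor-specific if it is called present (log2(RPKM+1) >= cutoff) in
at least ``min_tumor_lines`` tumor cell lines and ``min_primaries`` primary
tumors while absent from every normal sample ("acquired"), or — with the
same tumor presence requirement — present in normals but carrying at least
``enlarged_fold`` (2x) the mean signal in tumors compared to normals
("enlarged"). Signal comparison uses the depth-normalized input-subtracted
score, which is the depth-comparable unit of "sequencing reads in the
region".
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import SampleInfo
from .scoring import ScoreMatrix

__all__ = ["call_tumor_specific", "tumor_specific_genes"]


def call_tumor_specific(
    presence: pd.DataFrame,
    scores: ScoreMatrix,
    samples: Sequence[SampleInfo],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Call acquired and enlarged tumor-specific SEs.

    ``presence`` is the boolean element x sample matrix. Acquired calls take
    precedence over enlarged when both criteria hold. Fold is the ratio of
    mean tumor score (cell lines + primaries) to mean normal score, with the
    fold test inclusive at exactly ``enlarged_fold``.
    """
    config = config or PipelineConfig()
    by_cat: dict[str, list[str]] = {"tumor_cell_line": [], "primary_tumor": [], "normal": []}
    for s in samples:
        by_cat[s.category].append(s.sample_id)
    if not by_cat["normal"]:
        raise ValueError("no normal samples in metadata; tumor-specificity undefined")
    lines, primaries, normals = (
        by_cat["tumor_cell_line"],
        by_cat["primary_tumor"],
        by_cat["normal"],
    )
    tumors = lines + primaries
    rows = []
    for element in presence.index:
        pres = presence.loc[element]
        n_lines = int(pres[lines].sum())
        n_prim = int(pres[primaries].sum())
        n_norm = int(pres[normals].sum())
        if n_lines < config.min_tumor_lines or n_prim < config.min_primaries:
            continue
        tumor_mean = float(scores.values.loc[element, tumors].mean())
        normal_mean = float(scores.values.loc[element, normals].mean())
        if normal_mean > 0:
            fold = tumor_mean / normal_mean
        else:
            fold = np.inf if tumor_mean > 0 else 0.0
        if n_norm == 0:
            mode = "acquired"
        elif fold >= config.enlarged_fold:
            mode = "enlarged"
        else:
            continue
        rows.append(
            {
                "element": element,
                "mode": mode,
                "n_tumor_lines_present": n_lines,
                "n_primaries_present": n_prim,
                "n_normals_present": n_norm,
                "tumor_mean_signal": tumor_mean,
                "normal_mean_signal": normal_mean,
                "fold": fold,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "element",
            "mode",
            "n_tumor_lines_present",
            "n_primaries_present",
            "n_normals_present",
            "tumor_mean_signal",
            "normal_mean_signal",
            "fold",
        ],
    )
    return out.set_index("element")


def tumor_specific_genes(
    calls: pd.DataFrame, associations: pd.DataFrame
) -> list[str]:
    """Deduplicated, sorted union of genes associated with the called SEs."""
    genes: set[str] = set()
    assoc_by_element = associations.groupby("element")["gene"] if len(associations) else None
    for element in calls.index:
        if assoc_by_element is not None and element in associations["element"].values:
            genes.update(assoc_by_element.get_group(element))
        else:
            warnings.warn(f"tumor-specific SE {element} has no gene associations")
    return sorted(genes)
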