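"""Score every sample against the consensus map and call SE presence.

The score of a consensus element (or 20 kb bin) in a sample is its
input-subtracted RPKM: ChIP RPKM minus matched-input RPKM, floored at zero.
A sample is called positive for a superenhancer when
log2(score + 1) >= se_log_cutoff (default 6), the cross-sample threshold
adopted because the per-sample rank-curve cutoff varies between samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusBin, ConsensusElement
from .intervals import GenomicInterval
from .io import SampleInfo

__all__ = ["ScoreMatrix", "rpkm", "score_samples", "call_presence", "se_size"]


def rpkm(count: float, length: int, library: float) -> float:
    """Reads per kilobase of interval per million mapped reads."""
    if length <= 0:
        raise ValueError("interval length must be positive")
    if library <= 0:
        raise ValueError("library size must be positive")
    return count / ((length / 1e3) * (library / 1e6))


@dataclass
class ScoreMatrix:
    """Input-subtracted RPKM, features (elements or bins) x samples.

    values are floored at 0; ``log`` is log2(values + 1) elementwise.
    """

    values: pd.DataFrame
    intervals: dict[str, GenomicInterval]

    @property
    def log(self) -> pd.DataFrame:
        return np.log2(self.values + 1.0)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def score_samples(
    features: Sequence[ConsensusElement | ConsensusBin],
    samples: Sequence[SampleInfo],
    chip_counts: Mapping[str, Sequence[float]],
    input_counts: Mapping[str, Sequence[float]],
) -> ScoreMatrix:
    """Build the feature x sample score matrix.

    value(feature, sample) = max(0, chip RPKM - input RPKM). Counts must be
    aligned with ``features``; every sample needs both ChIP and input counts.
    """
    ids = [getattr(f, "element_id", None) or f.bin_id for f in features]
    intervals = {i: f.interval for i, f in zip(ids, features)}
    lengths = np.array([f.interval.length for f in features], dtype=float)
    columns = {}
    for sample in samples:
        if sample.sample_id not in chip_counts:
            raise ValueError(f"sample {sample.sample_id} missing ChIP counts")
        if sample.sample_id not in input_counts:
            raise ValueError(f"sample {sample.sample_id} missing input counts")
        chip = np.asarray(chip_counts[sample.sample_id], dtype=float)
        inp = np.asarray(input_counts[sample.sample_id], dtype=float)
        if chip.shape[0] != len(features) or inp.shape[0] != len(features):
            raise ValueError(f"counts for {sample.sample_id} do not align with features")
        chip_rpkm = chip / ((lengths / 1e3) * (sample.chip_library_size / 1e6))
        input_rpkm = inp / ((lengths / 1e3) * (sample.input_library_size / 1e6))
        columns[sample.sample_id] = np.maximum(0.0, chip_rpkm - input_rpkm)
    values = pd.DataFrame(columns, index=ids)
    return ScoreMatrix(values=values, intervals=intervals)


def call_presence(scores: ScoreMatrix, se_log_cutoff: float = 6.0) -> pd.DataFrame:
    """Boolean SE presence per feature x sample; threshold inclusive (>=)."""
    return scores.log >= se_log_cutoff


def se_size(scores: ScoreMatrix, parent_ids: Mapping[str, str]) -> pd.DataFrame:
    """Per-sample SE size surrogate: sum of bin scores per parent element.

    Consensus elements have fixed genomic width, so the only sample-varying
    notion of "size" is signal mass; this sum is what "SE size" means
    wherever it is correlated or ranked downstream. When ``scores`` is
    already element-level, pass the identity mapping.
    """
    parents = pd.Series({fid: parent_ids[fid] for fid in scores.feature_ids})
    sized = scores.values.groupby(parents).sum()
    sized.index.name = scores.values.index.name
    return sized
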