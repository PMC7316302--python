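"""Per-sample enhancer stitching, signal ranking and superenhancer calling.

The procedure mirrors the classic rank-ordering approach: peaks within a
stitching distance of each other are merged into candidate regions, regions
are scored by depth-adjusted, input-subtracted ChIP signal, ranked, and the
regions beyond the inflection point of the ranked-signal curve are called
superenhancers. The inflection point is computed as the point where a line
of slope 1 is tangent to the min-max-scaled curve, i.e. argmax(x - y): an
exact, deterministic equivalent of the usual graphical definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, sort_intervals

__all__ = [
    "StitchedRegion",
    "RankedEnhancerTable",
    "filter_peaks",
    "stitch_peaks",
    "score_regions",
    "classify_superenhancers",
]


def filter_peaks(
    peaks: Sequence[GenomicInterval],
    min_size: int | None = None,
    min_enrichment: float | None = None,
    enrichment: Sequence[float] | None = None,
) -> list[GenomicInterval]:
    """Optional pre-stitching peak filter (off unless thresholds are given).

    Upstream peak callers are sometimes post-filtered by size or by
    ChIP/input enrichment before stitching; the appropriate thresholds are
    dataset-specific, so none are defaulted here. ``enrichment`` must align
    with ``peaks`` when ``min_enrichment`` is used.
    """
    kept = list(peaks)
    if min_size is not None:
        kept = [p for p in kept if p.length >= min_size]
    if min_enrichment is not None:
        if enrichment is None or len(enrichment) != len(peaks):
            raise ValueError("min_enrichment requires per-peak enrichment values")
        by_peak = dict(zip(peaks, enrichment))
        kept = [p for p in kept if by_peak[p] >= min_enrichment]
    return kept


@dataclass(frozen=True)
class StitchedRegion:
    """A stitched enhancer region spanning its constituent peaks."""

    interval: GenomicInterval
    constituents: tuple[GenomicInterval, ...]
    chip_signal: float | None = None
    rank: int | None = None


@dataclass(frozen=True)
class RankedEnhancerTable:
    """Regions ranked ascending by signal, with the SE cutoff rank.

    A region is a superenhancer iff its rank is above ``cutoff_rank``.
    """

    regions: tuple[StitchedRegion, ...]
    cutoff_rank: int

    @property
    def se_flags(self) -> np.ndarray:
        return np.array([r.rank > self.cutoff_rank for r in self.regions])

    @property
    def superenhancers(self) -> list[StitchedRegion]:
        return [r for r in self.regions if r.rank > self.cutoff_rank]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.interval.chrom for r in self.regions],
                "start": [r.interval.start for r in self.regions],
                "end": [r.interval.end for r in self.regions],
                "n_constituents": [len(r.constituents) for r in self.regions],
                "signal": [r.chip_signal for r in self.regions],
                "rank": [r.rank for r in self.regions],
                "is_SE": self.se_flags,
            }
        )


def _exclude_tss_peaks(
    peaks: list[GenomicInterval],
    tss: Sequence[GenomicInterval],
    tss_exclusion: int,
) -> list[GenomicInterval]:
    if tss_exclusion <= 0 or not tss:
        return peaks
    windows = sort_intervals(
        GenomicInterval(t.chrom, max(0, t.start - tss_exclusion), t.end + tss_exclusion)
        for t in tss
    )
    kept = []
    for peak in peaks:
        inside = any(
            w.chrom == peak.chrom and w.start <= peak.start and peak.end <= w.end
            for w in windows
        )
        if not inside:
            kept.append(peak)
    return kept


def stitch_peaks(
    peaks: Sequence[GenomicInterval],
    stitch_distance: int = 12_500,
    tss: Sequence[GenomicInterval] | None = None,
    tss_exclusion: int = 0,
) -> list[StitchedRegion]:
    """Merge peaks whose gap is <= ``stitch_distance`` into stitched regions.

    The gap comparison is inclusive ("within 12.5 kb"); overlapping peaks
    always merge. With ``tss_exclusion`` > 0, peaks fully inside a TSS window
    are removed before stitching; the default of 0 disables the exclusion.
    """
    if stitch_distance < 0:
        raise ValueError("stitch_distance must be non-negative")
    remaining = _exclude_tss_peaks(list(peaks), tss or [], tss_exclusion)
    ordered = sort_intervals(remaining)
    regions: list[StitchedRegion] = []
    group: list[GenomicInterval] = []

    def flush() -> None:
        if group:
            span = GenomicInterval(group[0].chrom, group[0].start, max(p.end for p in group))
            regions.append(StitchedRegion(span, tuple(group)))

    current_end = None
    for peak in ordered:
        if group and peak.chrom == group[0].chrom and peak.start - current_end <= stitch_distance:
            group.append(peak)
            current_end = max(current_end, peak.end)
        else:
            flush()
            group = [peak]
            current_end = peak.end
    flush()
    return regions


def score_regions(
    regions: Sequence[StitchedRegion],
    chip_counts: Sequence[float],
    input_counts: Sequence[float],
    chip_library: float,
    input_library: float,
) -> list[StitchedRegion]:
    """Attach depth-adjusted, input-subtracted signal to each region.

    signal = max(0, chip / (chip_library/1e6) - input / (input_library/1e6)),
    i.e. reads-per-million ChIP minus reads-per-million input, floored at 0
    (negative enhancer signal is not meaningful and breaks the log transforms
    used downstream).
    """
    if len(chip_counts) != len(regions) or len(input_counts) != len(regions):
        raise ValueError("counts must align one-to-one with regions")
    if chip_library <= 0 or input_library <= 0:
        raise ValueError("library sizes must be positive")
    chip = np.asarray(chip_counts, dtype=float) / (chip_library / 1e6)
    inp = np.asarray(input_counts, dtype=float) / (input_library / 1e6)
    signal = np.maximum(0.0, chip - inp)
    return [replace(r, chip_signal=float(s)) for r, s in zip(regions, signal)]


def classify_superenhancers(regions: Sequence[StitchedRegion]) -> RankedEnhancerTable:
    """Rank regions by signal and call SEs beyond the curve's inflection point.

    Ranks (1-based) ascend with signal, ties broken by genomic position. With
    ranks scaled to x in [0,1] and signals to y in [0,1], the cutoff rank is
    argmax(x - y) — the slope-1 tangent point — and every region ranked above
    it is a superenhancer. A flat curve (all signals equal) yields no SEs.
    """
    if len(regions) < 2:
        raise ValueError("need at least 2 scored regions to rank")
    if any(r.chip_signal is None for r in regions):
        raise ValueError("regions must be scored before classification")
    ordered = sorted(
        regions,
        key=lambda r: (r.chip_signal, r.interval.chrom, r.interval.start),
    )
    n = len(ordered)
    signals = np.array([r.chip_signal for r in ordered], dtype=float)
    lo, hi = signals[0], signals[-1]
    if hi == lo:
        warnings.warn("all region signals equal; degenerate curve, calling no SEs")
        cutoff = n
    else:
        x = np.arange(n) / (n - 1)
        y = (signals - lo) / (hi - lo)
        cutoff = int(np.argmax(x - y)) + 1  # 1-based rank at the tangent point
    ranked = tuple(replace(r, rank=i + 1) for i, r in enumerate(ordered))
    return RankedEnhancerTable(regions=ranked, cutoff_rank=cutoff)
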