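"""Cross-sample consensus maps of enhancers and superenhancers.

Per-sample calls are consolidated by transitive merging of intervals that
share at least ``min_overlap`` bases (5 kb for superenhancers, 10 bp for
typical enhancers). Enhancer-class consensus elements overlapping a TSS are
removed entirely; SE elements keep TSS overlaps. Consensus SEs are split
into fixed-width bins (20 kb) for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval

__all__ = [
    "ConsensusElement",
    "ConsensusBin",
    "consolidate",
    "subtract_tss",
    "bin_elements",
]


@dataclass(frozen=True)
class ConsensusElement:
    element_id: str
    interval: GenomicInterval
    klass: str  # "enhancer" | "superenhancer"
    samples: frozenset[str]


@dataclass(frozen=True)
class ConsensusBin:
    bin_id: str
    interval: GenomicInterval
    parent_id: str


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def consolidate(
    per_sample_elements: Mapping[str, Sequence[GenomicInterval]],
    klass: str,
    min_overlap: int,
) -> list[ConsensusElement]:
    """Merge per-sample intervals that overlap by >= ``min_overlap`` bases.

    Merging is the transitive closure of the pairwise overlap relation; the
    merged interval is the span of the merged set and contributing samples
    are the union. "Minimum overlap" means required shared bases (bedtools
    merge with a negative -d), not an allowed gap.
    """
    if klass not in ("enhancer", "superenhancer"):
        raise ValueError(f"unknown element class {klass!r}")
    if min_overlap <= 0:
        raise ValueError("min_overlap must be positive")
    items: list[tuple[GenomicInterval, str]] = []
    for sample_id, elements in per_sample_elements.items():
        for iv in elements:
            items.append((iv, sample_id))
    if not items:
        return []
    items.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    uf = _UnionFind(len(items))
    # Sorted sweep: element j (start >= start_i) overlaps i by >= min_overlap
    # iff min(end_i, end_j) - start_j >= min_overlap.
    for i, (iv_i, _) in enumerate(items):
        for j in range(i + 1, len(items)):
            iv_j = items[j][0]
            if iv_j.chrom != iv_i.chrom or iv_j.start > iv_i.end - min_overlap:
                break
            if min(iv_i.end, iv_j.end) - iv_j.start >= min_overlap:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for idx in range(len(items)):
        groups.setdefault(uf.find(idx), []).append(idx)
    prefix = "se" if klass == "superenhancer" else "enh"
    merged: list[ConsensusElement] = []
    spans = []
    for members in groups.values():
        ivs = [items[m][0] for m in members]
        samples = frozenset(items[m][1] for m in members)
        span = GenomicInterval(ivs[0].chrom, min(v.start for v in ivs), max(v.end for v in ivs))
        spans.append((span, samples))
    spans.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    for k, (span, samples) in enumerate(spans):
        merged.append(
            ConsensusElement(
                element_id=f"{prefix}_{k:05d}",
                interval=span,
                klass=klass,
                samples=samples,
            )
        )
    return merged


def subtract_tss(
    elements: Sequence[ConsensusElement],
    tss_intervals: Iterable[GenomicInterval],
) -> list[ConsensusElement]:
    """Drop every element overlapping a TSS interval by >= 1 bp.

    Whole elements are removed, not trimmed (applies to the enhancer-class
    consensus; SEs keep their TSS overlaps).
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in tss_intervals:
        by_chrom.setdefault(t.chrom, []).append(t)
    kept = []
    for el in elements:
        hits = by_chrom.get(el.interval.chrom, ())
        if not any(el.interval.overlap(t) > 0 for t in hits):
            kept.append(el)
    return kept


def bin_elements(
    elements: Sequence[ConsensusElement], bin_width: int
) -> list[ConsensusBin]:
    """Split each element into ``bin_width`` bins; the last bin is truncated.

    Binning conserves territory: the concatenated bins of an element
    reconstruct it exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    bins: list[ConsensusBin] = []
    for el in elements:
        start = el.interval.start
        idx = 0
        while start < el.interval.end:
            end = min(start + bin_width, el.interval.end)
            bins.append(
                ConsensusBin(
                    bin_id=f"{el.element_id}:bin{idx}",
                    interval=GenomicInterval(el.interval.chrom, start, end),
                    parent_id=el.element_id,
                )
            )
            start = end
            idx += 1
    return bins
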