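"""Genomic interval primitives and step-function coverage.

All coordinates are 0-based half-open (BED convention); strand is ignored
throughout, since H3K27Ac signal is unstranded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["GenomicInterval", "Coverage", "sort_intervals"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap(self, other: "GenomicInterval") -> int | None:
        """Distance in bp between the closest edges; 0 if overlapping.

        Returns None for intervals on different chromosomes, where no
        genomic distance is defined.
        """
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


class Coverage:
    """Per-base coverage as a sparse step function, one track per chromosome.

    Values are real-valued depths (reads per base), so both raw pileups and
    normalized tracks are representable. Interval sums are exact integrals of
    the step function and equal per-base summation.
    """

    def __init__(self, segments: Mapping[str, Sequence[tuple[int, int, float]]]):
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        self._warned: set[str] = set()
        for chrom, segs in segments.items():
            if not len(segs):
                continue
            arr = np.asarray(segs, dtype=float)
            order = np.argsort(arr[:, 0], kind="stable")
            arr = arr[order]
            starts, ends, values = arr[:, 0], arr[:, 1], arr[:, 2]
            if np.any(ends <= starts):
                raise ValueError(f"empty coverage segment on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping coverage segments on {chrom}")
            # cumulative signal mass up to the start of each segment
            masses = values * (ends - starts)
            cum = np.concatenate([[0.0], np.cumsum(masses)])
            self._chroms[chrom] = (starts, ends, values, cum)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chroms)

    def total_mass(self) -> float:
        """Integral of coverage over the genome (== total reads for a pileup)."""
        return float(sum(cum[-1] for _, _, _, cum in self._chroms.values()))

    def _mass_to(self, chrom: str, pos: float) -> float:
        starts, ends, values, cum = self._chroms[chrom]
        idx = int(np.searchsorted(starts, pos, side="right")) - 1
        if idx < 0:
            return 0.0
        inside = min(max(pos - starts[idx], 0.0), ends[idx] - starts[idx])
        return float(cum[idx] + values[idx] * inside)

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum over bases of per-base coverage within [start, end)."""
        if chrom not in self._chroms:
            if chrom not in self._warned:
                warnings.warn(
                    f"chromosome {chrom!r} absent from coverage; counting 0",
                    stacklevel=2,
                )
                self._warned.add(chrom)
            return 0.0
        return self._mass_to(chrom, end) - self._mass_to(chrom, start)

    def interval_sums(self, intervals: Iterable[GenomicInterval]) -> np.ndarray:
        return np.array(
            [self.interval_sum(iv.chrom, iv.start, iv.end) for iv in intervals],
            dtype=float,
        )
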