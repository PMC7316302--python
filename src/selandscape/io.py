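"""Readers and writers for the plain-text formats every stage touches.

BED3/BED6 for intervals, bedGraph for coverage, TSV with a header row for
matrices (first column = feature id), and a TSV sample sheet. All interval
I/O is 0-based half-open; anything 1-based must be converted before it gets
here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import Coverage, GenomicInterval

__all__ = [
    "SampleInfo",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_coverage",
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
]

CATEGORIES = ("tumor_cell_line", "primary_tumor", "normal")


@dataclass(frozen=True)
class SampleInfo:
    """One profiled sample: identity, biological category and library depths."""

    sample_id: str
    category: str
    subtype: str
    chip_library_size: float
    input_library_size: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category {self.category!r} for {self.sample_id} not one of {CATEGORIES}"
            )
        if self.chip_library_size <= 0 or self.input_library_size <= 0:
            raise ValueError(f"library sizes for {self.sample_id} must be > 0")


class BedParseError(ValueError):
    pass


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse a BED3+ file; name (column 4) is kept when present.

    Input order is preserved. Malformed lines raise with the line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else None
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(
    path: str | Path,
    intervals: Iterable[GenomicInterval],
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED3 (or BED5 when names/scores are present)."""
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or scores is not None:
                fields.append(iv.name if iv.name is not None else f"region_{i}")
            if scores is not None:
                fields.append(f"{scores[i]:g}")
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path: str | Path) -> Coverage:
    """Load a sorted bedGraph into a step-function Coverage."""
    segments: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: malformed bedGraph line") from exc
            segments.setdefault(fields[0], []).append((start, end, value))
    return Coverage(segments)


def write_bedgraph(
    path: str | Path, segments: dict[str, list[tuple[int, int, float]]]
) -> None:
    with open(path, "w") as fh:
        for chrom in segments:
            for start, end, value in sorted(segments[chrom]):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_coverage(path: str | Path, intervals: Iterable[GenomicInterval]) -> np.ndarray:
    """Per-interval read counts from a bedGraph coverage track.

    The count for an interval is the sum over its bases of per-base coverage;
    intervals on chromosomes absent from the track count 0 (with a warning).
    """
    return read_bedgraph(path).interval_sums(intervals)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """TSV with header row; first column is the feature id index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(path: str | Path, matrix: pd.DataFrame, index_label: str = "id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_metadata(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "category", "subtype", "chip_library_size", "input_library_size"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns {sorted(missing)}")
    return [
        SampleInfo(
            sample_id=str(row.sample_id),
            category=str(row.category),
            subtype=str(row.subtype),
            chip_library_size=float(row.chip_library_size),
            input_library_size=float(row.input_library_size),
        )
        for row in df.itertuples()
    ]


def write_metadata(path: str | Path, samples: Iterable[SampleInfo]) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "category": s.category,
                "subtype": s.subtype,
                "chip_library_size": s.chip_library_size,
                "input_library_size": s.input_library_size,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)
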