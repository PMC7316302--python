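"""Pipeline configuration: every numeric knob of the analysis in one place.

Defaults reproduce the study's published parameter set (ROSE stitching at
12.5 kb with TSS exclusion off, 5 kb / 10 bp consensus merge overlaps, 20 kb
bins, the log2(RPKM+1) >= 6 superenhancer presence threshold, top-10%
variance selection with k=10 average-linkage clustering, the 10 Mb / r >= 0.6
gene association rule, the >= 4 cell lines + >= 1 primary + 0 normals
tumor-specificity filter with 2x enlargement, and the 8-guide / top-3 screen
scoring with control-anchored normalization and -0.5 cutoffs).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    stitch_distance: int = 12_500
    tss_exclusion: int = 0
    se_merge_overlap: int = 5_000
    enh_merge_overlap: int = 10
    bin_width: int = 20_000
    se_log_cutoff: float = 6.0
    variance_top_fraction: float = 0.10
    cluster_k: int = 10
    min_cluster_size: int = 3
    gene_window: int = 10_000_000
    corr_threshold: float = 0.6
    min_genes_per_se: int = 2
    min_tumor_lines: int = 4
    min_primaries: int = 1
    enlarged_fold: float = 2.0
    guides_per_gene: int = 8
    top_guides: int = 3
    hit_cutoff: float = -0.5
    ceres_cutoff: float = -0.5
    signature_size: int = 600
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "stitch_distance",
            "tss_exclusion",
            "se_merge_overlap",
            "enh_merge_overlap",
            "bin_width",
            "gene_window",
            "min_cluster_size",
            "min_tumor_lines",
            "min_primaries",
            "min_genes_per_se",
            "guides_per_gene",
            "top_guides",
            "cluster_k",
            "signature_size",
        ):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if not (0 < self.variance_top_fraction <= 1):
            raise ValueError(
                "variance_top_fraction must be in (0, 1], got "
                f"{self.variance_top_fraction}"
            )
        if self.top_guides > self.guides_per_gene:
            raise ValueError("top_guides cannot exceed guides_per_gene")
        if self.bin_width == 0:
            raise ValueError("bin_width must be positive")
        if self.enlarged_fold <= 0:
            raise ValueError("enlarged_fold must be positive")


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML ``key: value`` config; unset keys keep their defaults.

    Unknown keys raise (catching typos); invariants are re-checked after
    assignment.
    """
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping of key: value pairs")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
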