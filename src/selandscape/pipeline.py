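"""End-to-end orchestration over a study directory.

Stage order follows the study workflow: per-sample stitching/ranking/SE
calling, cross-sample consensus maps (SE and enhancer class), binning,
consensus scoring and presence calls, variance-based clustering,
SE-to-gene association, and tumor-specific SE calling. Each stage is also
callable on its own; the numbered analysis scripts and the CLI are thin
wrappers around these functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import consensus as cons
from . import genemap, rose, scoring, tumor
from .config import PipelineConfig
from .intervals import Coverage, GenomicInterval
from .io import SampleInfo, read_bed, read_bedgraph, read_metadata

__all__ = ["Study", "StudyResult", "load_study", "call_sample_enhancers",
           "build_consensus_maps", "score_consensus", "cluster_samples",
           "run_pipeline"]


@dataclass
class Study:
    """In-memory view of a study directory."""

    samples: list[SampleInfo]
    peaks: dict[str, list[GenomicInterval]]
    chip: dict[str, Coverage]
    input_: dict[str, Coverage]
    tss: list[GenomicInterval] = field(default_factory=list)

    def sample(self, sample_id: str) -> SampleInfo:
        return next(s for s in self.samples if s.sample_id == sample_id)


def load_study(study_dir: str | Path) -> Study:
    """Read metadata, per-sample peak BEDs and coverage bedGraphs.

    Expects the layout written by the simulator / documented in the README:
    metadata.tsv, peaks/<sample>.peaks.bed, coverage/<sample>.{chip,input}.bedGraph
    and optionally tss.bed.
    """
    study_dir = Path(study_dir)
    samples = read_metadata(study_dir / "metadata.tsv")
    peaks, chip, input_ = {}, {}, {}
    for s in samples:
        peaks[s.sample_id] = read_bed(study_dir / "peaks" / f"{s.sample_id}.peaks.bed")
        chip[s.sample_id] = read_bedgraph(
            study_dir / "coverage" / f"{s.sample_id}.chip.bedGraph"
        )
        input_[s.sample_id] = read_bedgraph(
            study_dir / "coverage" / f"{s.sample_id}.input.bedGraph"
        )
    tss_path = study_dir / "tss.bed"
    tss = read_bed(tss_path) if tss_path.exists() else []
    return Study(samples=samples, peaks=peaks, chip=chip, input_=input_, tss=tss)


def call_sample_enhancers(
    study: Study, config: PipelineConfig | None = None
) -> dict[str, rose.RankedEnhancerTable]:
    """Stitch, score and rank each sample's peaks; call per-sample SEs."""
    config = config or PipelineConfig()
    tables: dict[str, rose.RankedEnhancerTable] = {}
    for s in study.samples:
        regions = rose.stitch_peaks(
            study.peaks[s.sample_id],
            stitch_distance=config.stitch_distance,
            tss=study.tss,
            tss_exclusion=config.tss_exclusion,
        )
        if len(regions) < 2:
            warnings.warn(f"{s.sample_id}: fewer than 2 stitched regions; skipping")
            continue
        ivs = [r.interval for r in regions]
        chip_counts = study.chip[s.sample_id].interval_sums(ivs)
        input_counts = study.input_[s.sample_id].interval_sums(ivs)
        scored = rose.score_regions(
            regions, chip_counts, input_counts, s.chip_library_size, s.input_library_size
        )
        tables[s.sample_id] = rose.classify_superenhancers(scored)
    return tables


def build_consensus_maps(
    study: Study,
    rose_tables: dict[str, rose.RankedEnhancerTable],
    config: PipelineConfig | None = None,
) -> tuple[list[cons.ConsensusElement], list[cons.ConsensusElement], list[cons.ConsensusBin]]:
    """Cross-sample SE and enhancer consensus plus SE bins.

    The SE consensus merges per-sample SE calls at >= 5 kb overlap; the
    enhancer consensus merges the raw peak calls at >= 10 bp overlap and
    then drops TSS-overlapping elements. SEs keep TSS overlaps.
    """
    config = config or PipelineConfig()
    se_by_sample = {
        sid: [r.interval for r in table.superenhancers]
        for sid, table in rose_tables.items()
    }
    se_elements = cons.consolidate(se_by_sample, "superenhancer", config.se_merge_overlap)
    enh_by_sample = {s.sample_id: study.peaks[s.sample_id] for s in study.samples}
    enh_elements = cons.consolidate(enh_by_sample, "enhancer", config.enh_merge_overlap)
    enh_elements = cons.subtract_tss(enh_elements, study.tss)
    bins = cons.bin_elements(se_elements, config.bin_width)
    return se_elements, enh_elements, bins


def score_consensus(
    study: Study,
    se_elements: list[cons.ConsensusElement],
    bins: list[cons.ConsensusBin],
    config: PipelineConfig | None = None,
) -> dict:
    """Score all samples against the consensus SE map.

    Returns element-level and bin-level score matrices, the element-level
    presence matrix and the per-element SE sizes (sum of bin scores).
    """
    config = config or PipelineConfig()
    features = list(se_elements) + list(bins)
    chip_counts, input_counts = {}, {}
    for s in study.samples:
        ivs = [f.interval for f in features]
        chip_counts[s.sample_id] = study.chip[s.sample_id].interval_sums(ivs)
        input_counts[s.sample_id] = study.input_[s.sample_id].interval_sums(ivs)
    matrix = scoring.score_samples(features, study.samples, chip_counts, input_counts)
    n_el = len(se_elements)
    element_scores = scoring.ScoreMatrix(
        values=matrix.values.iloc[:n_el], intervals=matrix.intervals
    )
    bin_scores = scoring.ScoreMatrix(
        values=matrix.values.iloc[n_el:], intervals=matrix.intervals
    )
    presence = scoring.call_presence(element_scores, config.se_log_cutoff)
    parent = {b.bin_id: b.parent_id for b in bins}
    sizes = scoring.se_size(bin_scores, parent)
    sizes = sizes.reindex([e.element_id for e in se_elements]).fillna(0.0)
    return {
        "element_scores": element_scores,
        "bin_scores": bin_scores,
        "presence": presence,
        "sizes": sizes,
    }


def cluster_samples(
    sizes: pd.DataFrame,
    config: PipelineConfig | None = None,
    restrict_to: list[str] | None = None,
    diagnostics_range: range | None = range(2, 13),
) -> tuple[cl.ClusterAssignment, list[str]]:
    """Variance selection, sample correlation and UPGMA clustering."""
    config = config or PipelineConfig()
    selected = cl.top_variable(sizes, config.variance_top_fraction, restrict_to)
    log_sizes = np.log2(sizes.loc[selected] + 1.0)
    corr = cl.correlate_samples(log_sizes)
    assignment = cl.hierarchical_cluster(
        corr,
        k=min(config.cluster_k, len(corr)),
        min_cluster_size=config.min_cluster_size,
        diagnostics_range=diagnostics_range,
    )
    return assignment, selected


@dataclass
class StudyResult:
    rose_tables: dict[str, rose.RankedEnhancerTable]
    se_elements: list[cons.ConsensusElement]
    enh_elements: list[cons.ConsensusElement]
    bins: list[cons.ConsensusBin]
    element_scores: scoring.ScoreMatrix
    bin_scores: scoring.ScoreMatrix
    presence: pd.DataFrame
    sizes: pd.DataFrame
    assignment: cl.ClusterAssignment
    selected: list[str]
    group_specific: pd.DataFrame | None
    associations: pd.DataFrame | None
    tumor_calls: pd.DataFrame
    tumor_genes: list[str]


def run_pipeline(
    study_dir: str | Path,
    config: PipelineConfig | None = None,
    expression: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    restrict_variance_to: list[str] | None = None,
) -> StudyResult:
    """Full landscape analysis of a study directory.

    ``expression`` (gene x sample RPKM) and ``genes`` (gene_id/chrom/
    start/end spans) unlock the SE-to-gene association stage; without them
    tumor-specific SEs are still called but carry no gene list.
    """
    config = config or PipelineConfig()
    study = load_study(study_dir)
    rose_tables = call_sample_enhancers(study, config)
    se_elements, enh_elements, bins = build_consensus_maps(study, rose_tables, config)
    scored = score_consensus(study, se_elements, bins, config)
    assignment, selected = cluster_samples(
        scored["sizes"], config, restrict_to=restrict_variance_to
    )
    group_specific = None
    if len(assignment.cluster_labels) >= 2:
        log_sizes = np.log2(scored["sizes"] + 1.0)
        group_specific = cl.assign_group_specific(log_sizes, assignment)
    associations = None
    if expression is not None and genes is not None:
        cell_lines = [s.sample_id for s in study.samples if s.category == "tumor_cell_line"]
        intervals = {e.element_id: e.interval for e in se_elements}
        associations = genemap.associate_all(
            scored["sizes"],
            intervals,
            genes,
            expression,
            samples=cell_lines,
            window=config.gene_window,
            corr_threshold=config.corr_threshold,
            min_genes=config.min_genes_per_se,
        )
    tumor_calls = tumor.call_tumor_specific(
        scored["presence"], scored["element_scores"], study.samples, config
    )
    tumor_genes = (
        tumor.tumor_specific_genes(tumor_calls, associations)
        if associations is not None
        else []
    )
    return StudyResult(
        rose_tables=rose_tables,
        se_elements=se_elements,
        enh_elements=enh_elements,
        bins=bins,
        element_scores=scored["element_scores"],
        bin_scores=scored["bin_scores"],
        presence=scored["presence"],
        sizes=scored["sizes"],
        assignment=assignment,
        selected=selected,
        group_specific=group_specific,
        associations=associations,
        tumor_calls=tumor_calls,
        tumor_genes=tumor_genes,
    )
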