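"""Synthetic miniature study with planted ground truth for every stage.

The generator emulates the structure of a breast-cancer H3K27Ac cohort at
desk scale: tumor cell lines organised in clusters, primary-tumor clusters,
normal mammary-epithelial samples and a few "outlier" samples with
idiosyncratic landscapes (which the clustering step should leave
unassigned). Planted superenhancer classes:

* shared SEs present in every sample,
* cluster-specific SEs owned by one sample cluster (one high-signal
  "marker" SE per cluster so the top-variance selection always carries
  every cluster's identity),
* tumor-specific SEs owned by >= 4 cell lines of one cluster plus one
  primary-tumor cluster and absent from normals ("acquired"), two of which
  are instead present in normals at a third of the tumor signal
  ("enlarged", exercising the 2x rule),
* normal-only SEs,
* ubiquitous typical enhancers far below the SE threshold.

ChIP coverage is Poisson background plus boxcar enrichment over the
constituent peaks of owned elements; input is background only. Expression
is linear in log2(SE size) for planted SE-gene pairs with noise tuned to a
target correlation; screen counts are negative-binomial with essential-gene
and planted-dependency depletion carried by a subset of efficacious guides.

The genome is split into more, shorter chromosomes (8 x 2.5 Mb) than a real
one so that the 10 Mb gene-association window spans a whole chromosome:
elements sharing a cell-line ownership pattern are placed on different
chromosomes from each other's target genes, which makes exact
planted-association recovery well-defined. Everything is deterministic
given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .intervals import GenomicInterval
from .io import SampleInfo, write_bed, write_bedgraph, write_matrix, write_metadata

__all__ = [
    "PlantedElement",
    "PlantedGene",
    "PlantedLandscape",
    "ScreenSim",
    "simulate_landscape",
    "emit_sample_files",
    "simulate_expression",
    "simulate_screen",
    "simulate_dependency_scores",
]

SE_SPAN = 18_000
PEAK_WIDTH = 2_400
TYPICAL_WIDTH = 1_500
ELEMENT_MARGIN = 30_000
TYPICAL_MARGIN = 15_500
GENE_OFFSET = 5_000
GENE_LENGTH = 1_000
WINDOW = 10_000  # background-noise window width
ENLARGED_PLANTED_FOLD = 3.0


@dataclass(frozen=True)
class PlantedElement:
    element_id: str
    interval: GenomicInterval
    constituents: tuple[GenomicInterval, ...]
    klass: str
    owners: frozenset[str]
    cluster: str | None
    level: float  # target input-subtracted RPKM in owner samples
    enlarged: bool = False
    gene_id: str | None = None


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    interval: GenomicInterval
    element_id: str | None  # None for background genes


@dataclass
class PlantedLandscape:
    genome: list[tuple[str, int]]
    samples: list[SampleInfo]
    elements: list[PlantedElement]
    genes: list[PlantedGene]
    truth_labels: dict[str, str | None]
    associations: list[tuple[str, str, float]]  # (element, gene, target r)
    dependencies: dict[str, tuple[str, ...]]  # gene -> dependent cell lines
    screen_lines: list[str]
    screen_normal_line: str
    background_rate: float
    signal_scale: float
    false_positive_peaks: int
    seed: int
    free_zones: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def cell_lines(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.category == "tumor_cell_line"]

    @property
    def primaries(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.category == "primary_tumor"]

    @property
    def normals(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.category == "normal"]

    @property
    def genome_size(self) -> int:
        return sum(length for _, length in self.genome)

    @property
    def nominal_library(self) -> float:
        return self.background_rate * self.genome_size

    def se_elements(self) -> list[PlantedElement]:
        return [e for e in self.elements if e.klass != "typical_enhancer"]

    def tumor_specific_elements(self) -> list[PlantedElement]:
        return [e for e in self.elements if e.klass == "tumor_specific_SE"]

    def planted_value(self, element: PlantedElement, sample_id: str) -> float:
        """Deterministic planted input-subtracted RPKM of element in sample."""
        if sample_id not in element.owners:
            return 0.0
        idx = self.sample_ids.index(sample_id)
        base = element.level
        if element.enlarged:
            category = self.samples[idx].category
            if category == "normal":
                base = element.level / ENLARGED_PLANTED_FOLD
            mod = 1.0 + 0.25 * (1 if idx % 2 == 0 else -1)
        elif element.klass == "shared_SE":
            mod = 1.0 + 0.20 * (1 if idx % 2 == 0 else -1)
        else:
            mod = 1.0
        return base * mod * self.signal_scale

    def planted_size_matrix(self) -> pd.DataFrame:
        """Planted per-sample SE sizes (elements x samples)."""
        data = {
            sid: [self.planted_value(e, sid) for e in self.se_elements()]
            for sid in self.sample_ids
        }
        return pd.DataFrame(data, index=[e.element_id for e in self.se_elements()])


def _se_constituents(chrom: str, start: int, n_peaks: int) -> tuple[GenomicInterval, ...]:
    # n_peaks boxcars of PEAK_WIDTH spanning exactly SE_SPAN; gaps are equal
    # (integer division) and always far below the stitching distance
    gap = (SE_SPAN - n_peaks * PEAK_WIDTH) // (n_peaks - 1)
    peaks = []
    for i in range(n_peaks - 1):
        pos = start + i * (PEAK_WIDTH + gap)
        peaks.append(GenomicInterval(chrom, pos, pos + PEAK_WIDTH))
    peaks.append(GenomicInterval(chrom, start + SE_SPAN - PEAK_WIDTH, start + SE_SPAN))
    return tuple(peaks)


def simulate_landscape(
    config: PipelineConfig | None = None,
    *,
    lines_per_cluster: int = 4,
    n_line_clusters: int = 4,
    primaries_per_cluster: int = 4,
    n_primary_clusters: int = 2,
    n_outlier_lines: int = 2,
    n_outlier_primaries: int = 1,
    n_normals: int = 4,
    n_shared: int = 26,
    cs_per_cluster: int = 4,
    n_tumor_specific: int = 8,
    n_enlarged: int = 2,
    n_normal_only: int = 5,
    privates_per_outlier: int = 3,
    n_typical: int = 260,
    n_background_genes: int = 40,
    association_r: float = 0.95,
    background_rate: float = 0.5,
    signal_scale: float = 1.0,
    false_positive_peaks: int = 2,
    n_chromosomes: int = 8,
    chromosome_length: int = 2_500_000,
    seed: int = 0,
) -> PlantedLandscape:
    """Build the planted landscape (sample sheet, elements, genes, truth).

    Deterministic given ``seed``. Raises if the requested elements do not
    fit on the genome with safe (> stitch distance) spacing.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))

    # ---- samples ------------------------------------------------------
    line_clusters = [f"C{i + 1}" for i in range(n_line_clusters)]
    primary_clusters = [f"P{n_line_clusters + i + 1}" for i in range(n_primary_clusters)]
    samples: list[SampleInfo] = []
    truth: dict[str, str | None] = {}
    cluster_members: dict[str, list[str]] = {}
    idx = 0
    for cl in line_clusters:
        cluster_members[cl] = []
        for _ in range(lines_per_cluster):
            idx += 1
            sid = f"TCL{idx:02d}"
            samples.append(SampleInfo(sid, "tumor_cell_line", "TNBC", 1.0, 1.0))
            truth[sid] = cl
            cluster_members[cl].append(sid)
    outlier_lines = []
    for _ in range(n_outlier_lines):
        idx += 1
        sid = f"TCL{idx:02d}"
        samples.append(SampleInfo(sid, "tumor_cell_line", "TNBC", 1.0, 1.0))
        truth[sid] = None
        outlier_lines.append(sid)
    pidx = 0
    for cl in primary_clusters:
        cluster_members[cl] = []
        for _ in range(primaries_per_cluster):
            pidx += 1
            sid = f"PT{pidx:02d}"
            samples.append(SampleInfo(sid, "primary_tumor", "TNBC", 1.0, 1.0))
            truth[sid] = cl
            cluster_members[cl].append(sid)
    outlier_primaries = []
    for _ in range(n_outlier_primaries):
        pidx += 1
        sid = f"PT{pidx:02d}"
        samples.append(SampleInfo(sid, "primary_tumor", "TNBC", 1.0, 1.0))
        truth[sid] = None
        outlier_primaries.append(sid)
    cluster_members["N"] = []
    for i in range(n_normals):
        sid = f"NORM{i + 1:02d}"
        samples.append(SampleInfo(sid, "normal", "HMEC", 1.0, 1.0))
        truth[sid] = "N"
        cluster_members["N"].append(sid)
    all_ids = [s.sample_id for s in samples]
    lines = [s.sample_id for s in samples if s.category == "tumor_cell_line"]
    prims = [s.sample_id for s in samples if s.category == "primary_tumor"]
    normals = cluster_members["N"]
    outliers = outlier_lines + outlier_primaries

    # ---- element descriptors -----------------------------------------
    # (klass, owners, cluster, enlarged, hi, has_gene, line_pattern_key)
    descs: list[dict] = []
    for k in range(n_shared):
        descs.append(
            dict(klass="shared_SE", owners=all_ids, cluster=None, hi=False, gene=False, key=None)
        )
    # cluster-specific: first element of each cluster is the hi marker
    for cl in line_clusters + primary_clusters:
        for j in range(cs_per_cluster):
            owners = list(cluster_members[cl])
            descs.append(
                dict(
                    klass="cluster_specific_SE",
                    owners=owners,
                    cluster=cl,
                    hi=(j == 0),
                    gene=cl in line_clusters,
                    key=cl if cl in line_clusters else None,
                )
            )
    for j in range(n_normal_only):
        descs.append(
            dict(
                klass="normal_only_SE",
                owners=list(normals),
                cluster="N",
                hi=(j == 0),
                gene=False,
                key=None,
            )
        )
    # tumor-specific: acquired elements pair one line cluster with one
    # primary cluster; enlarged elements are pan-tumor plus attenuated normals
    n_acquired = n_tumor_specific - n_enlarged
    if n_acquired < 2:
        raise ValueError("need at least 2 acquired tumor-specific SEs")
    patterns = []
    for j in range(n_acquired):
        lc = line_clusters[j % n_line_clusters]
        pc = primary_clusters[(j // n_line_clusters + j) % n_primary_clusters]
        patterns.append((lc, pc))
    # guarantee >= 2 elements on the first line cluster (the screen cluster)
    patterns[0] = (line_clusters[0], primary_clusters[0])
    patterns[1] = (line_clusters[0], primary_clusters[-1])
    for lc, pc in patterns:
        descs.append(
            dict(
                klass="tumor_specific_SE",
                owners=cluster_members[lc] + cluster_members[pc],
                cluster=None,
                hi=False,
                gene=True,
                key=lc,
                enlarged=False,
            )
        )
    for _ in range(n_enlarged):
        descs.append(
            dict(
                klass="tumor_specific_SE",
                owners=lines + prims + normals,
                cluster=None,
                hi=False,
                gene=False,
                key=None,
                enlarged=True,
            )
        )
    for o_idx, sid in enumerate(outliers):
        for _ in range(privates_per_outlier):
            descs.append(
                dict(
                    klass="cluster_specific_SE",
                    owners=[sid],
                    cluster=f"outlier:{sid}",
                    hi=False,
                    gene=False,
                    key=None,
                )
            )
    # outliers co-own two hi markers of different clusters, so their
    # landscapes are distinct on the top-variance features and they survive
    # correlation (outliers must absorb the extra tree cuts at k=10)
    hi_descs = [d for d in descs if d["hi"]]
    hi_clusters = [d["cluster"] for d in hi_descs]
    for o_idx, sid in enumerate(outliers):
        picks = [
            hi_clusters[(2 * o_idx) % len(hi_clusters)],
            hi_clusters[(2 * o_idx + 1) % len(hi_clusters)],
        ]
        for d in hi_descs:
            if d["cluster"] in picks:
                d["owners"] = list(d["owners"]) + [sid]

    # ---- signal levels ------------------------------------------------
    hi_levels = np.linspace(2300.0, 2500.0, len(hi_descs))
    non_hi = [d for d in descs if not d["hi"]]
    pool = np.linspace(150.0, 1000.0, len(non_hi))
    enlarged_descs = [d for d in non_hi if d.get("enlarged")]
    others = [d for d in non_hi if not d.get("enlarged")]
    # enlarged elements take the largest levels so their normal-sample
    # signal (level / 3) stays above the presence threshold
    for d, level in zip(enlarged_descs, pool[::-1][: len(enlarged_descs)]):
        d["level"] = float(level)
    rest_levels = pool[: len(pool) - len(enlarged_descs)]
    for d, level in zip(others, rng.permutation(rest_levels)):
        d["level"] = float(level)
    for d, level in zip(hi_descs, hi_levels):
        d["level"] = float(level)

    # ---- chromosome assignment ---------------------------------------
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    if n_chromosomes < 2:
        raise ValueError("need >= 2 chromosomes")
    gene_chroms = chroms[:-1]  # last chromosome carries no associated genes
    per_chrom: dict[str, list[dict]] = {c: [] for c in chroms}
    key_counter: dict[str, int] = {}
    rr = 0
    for d in descs:
        if d["klass"] == "normal_only_SE" or (
            d["klass"] == "cluster_specific_SE"
            and (d["cluster"] in primary_clusters or str(d["cluster"]).startswith("outlier:PT"))
        ):
            # zero variance across cell lines: keep away from associated genes
            per_chrom[chroms[-1]].append(d)
        elif d["key"] is not None:
            # one element per cell-line ownership pattern per chromosome, so
            # no gene sits within the window of a same-pattern sibling
            n = key_counter.get(d["key"], 0)
            if n >= len(gene_chroms):
                raise ValueError(
                    f"too many gene-bearing elements with pattern {d['key']}; "
                    "add chromosomes or reduce elements"
                )
            offset = (line_clusters + primary_clusters).index(d["key"])
            per_chrom[gene_chroms[(n + 2 * offset) % len(gene_chroms)]].append(d)
            key_counter[d["key"]] = n + 1
        else:
            per_chrom[gene_chroms[rr % len(gene_chroms)]].append(d)
            rr += 1

    # ---- placement ----------------------------------------------------
    elements: list[PlantedElement] = []
    genes: list[PlantedGene] = []
    associations: list[tuple[str, str, float]] = []
    cursors = {c: 60_000 for c in chroms}
    eid = gid = 0
    for chrom in chroms:
        for d in per_chrom[chrom]:
            start = cursors[chrom]
            n_peaks = int(rng.integers(4, 7))
            constituents = _se_constituents(chrom, start, n_peaks)
            span = GenomicInterval(chrom, start, start + SE_SPAN)
            eid += 1
            element_id = f"pe{eid:03d}"
            gene_id = None
            if d["gene"]:
                gid += 1
                gene_id = f"G{gid:03d}"
                gene_iv = GenomicInterval(
                    chrom, span.end + GENE_OFFSET, span.end + GENE_OFFSET + GENE_LENGTH, gene_id
                )
                genes.append(PlantedGene(gene_id, gene_iv, element_id))
                associations.append((element_id, gene_id, association_r))
            elements.append(
                PlantedElement(
                    element_id=element_id,
                    interval=span,
                    constituents=constituents,
                    klass=d["klass"],
                    owners=frozenset(d["owners"]),
                    cluster=d["cluster"],
                    level=d["level"],
                    enlarged=bool(d.get("enlarged", False)),
                    gene_id=gene_id,
                )
            )
            cursors[chrom] = span.end + ELEMENT_MARGIN
    # typical enhancers: single ubiquitous peaks well below the SE level
    for t in range(n_typical):
        chrom = chroms[t % len(chroms)]
        start = cursors[chrom]
        if start + TYPICAL_WIDTH + TYPICAL_MARGIN > chromosome_length - 200_000:
            raise ValueError("genome too small for requested elements; enlarge it")
        eid += 1
        iv = GenomicInterval(chrom, start, start + TYPICAL_WIDTH)
        elements.append(
            PlantedElement(
                element_id=f"pe{eid:03d}",
                interval=iv,
                constituents=(iv,),
                klass="typical_enhancer",
                owners=frozenset(all_ids),
                cluster=None,
                level=float(rng.uniform(5.0, 15.0)),
            )
        )
        cursors[chrom] = iv.end + TYPICAL_MARGIN
    # background genes with no planted association
    for b in range(n_background_genes):
        chrom = gene_chroms[b % len(gene_chroms)]
        start = cursors[chrom]
        gid += 1
        gene_id = f"G{gid:03d}"
        genes.append(
            PlantedGene(
                gene_id,
                GenomicInterval(chrom, start, start + GENE_LENGTH, gene_id),
                None,
            )
        )
        cursors[chrom] = start + GENE_LENGTH + 2_000
    free_zones = {}
    for chrom in chroms:
        zone_start = cursors[chrom] + 20_000
        if zone_start >= chromosome_length - 10_000:
            raise ValueError("genome too small for requested elements; enlarge it")
        free_zones[chrom] = (zone_start, chromosome_length - 5_000)

    # ---- dependencies / screen design --------------------------------
    screen_cluster = line_clusters[0]
    dependencies: dict[str, tuple[str, ...]] = {}
    for e in elements:
        if (
            e.klass == "tumor_specific_SE"
            and not e.enlarged
            and e.gene_id is not None
            and set(cluster_members[screen_cluster]) <= set(e.owners)
        ):
            dependencies[e.gene_id] = tuple(cluster_members[screen_cluster])

    return PlantedLandscape(
        genome=[(c, chromosome_length) for c in chroms],
        samples=samples,
        elements=elements,
        genes=genes,
        truth_labels=truth,
        associations=associations,
        dependencies=dependencies,
        screen_lines=list(cluster_members[screen_cluster]),
        screen_normal_line=normals[0],
        background_rate=background_rate,
        signal_scale=signal_scale,
        false_positive_peaks=false_positive_peaks,
        seed=int(seed),
        free_zones=free_zones,
    )


# ----------------------------------------------------------------------
# emission of study files


def _sample_coverage(
    landscape: PlantedLandscape,
    sample_id: str,
    rng: np.random.Generator,
) -> tuple[dict, dict, float, float]:
    """Background + boxcar coverage for one sample; returns chip segments,
    input segments and their total masses."""
    rate = landscape.background_rate
    lib0 = landscape.nominal_library
    # enrichment depth per owned constituent
    enrich: dict[str, list[tuple[int, int, float]]] = {}
    for element in landscape.elements:
        value = landscape.planted_value(element, sample_id)
        if value <= 0:
            continue
        peak_total = sum(p.length for p in element.constituents)
        depth = value * (element.interval.length / 1e3) * (lib0 / 1e6) / peak_total
        for p in element.constituents:
            enrich.setdefault(p.chrom, []).append((p.start, p.end, depth))
    chip_segments: dict[str, list[tuple[int, int, float]]] = {}
    input_segments: dict[str, list[tuple[int, int, float]]] = {}
    chip_mass = input_mass = 0.0
    for chrom, length in landscape.genome:
        n_windows = length // WINDOW
        bg_chip = rng.poisson(rate * WINDOW, size=n_windows) / WINDOW
        bg_input = rng.poisson(rate * WINDOW, size=n_windows) / WINDOW
        input_segments[chrom] = [
            (w * WINDOW, (w + 1) * WINDOW, float(bg_input[w])) for w in range(n_windows)
        ]
        input_mass += float(bg_input.sum() * WINDOW)
        peaks = sorted(enrich.get(chrom, []))
        bounds = sorted(
            {w * WINDOW for w in range(n_windows + 1)}
            | {p[0] for p in peaks}
            | {p[1] for p in peaks}
        )
        segs = []
        pi = 0
        for lo, hi_b in zip(bounds[:-1], bounds[1:]):
            depth = float(bg_chip[min(lo // WINDOW, n_windows - 1)])
            while pi < len(peaks) and peaks[pi][1] <= lo:
                pi += 1
            if pi < len(peaks) and peaks[pi][0] <= lo < peaks[pi][1]:
                depth += peaks[pi][2]
            if depth > 0:
                segs.append((lo, hi_b, depth))
            chip_mass += depth * (hi_b - lo)
        chip_segments[chrom] = segs
    return chip_segments, input_segments, chip_mass, input_mass


@dataclass
class StudyFiles:
    study_dir: Path
    metadata: Path
    peaks: dict[str, Path]
    chip_coverage: dict[str, Path]
    input_coverage: dict[str, Path]
    genes_bed: Path
    tss_bed: Path
    truth_json: Path
    samples: list[SampleInfo]


def emit_sample_files(landscape: PlantedLandscape, out_dir: str | Path) -> StudyFiles:
    """Write the study directory: per-sample peak BEDs and ChIP/input
    bedGraphs, sample sheet, gene annotation and ground truth.

    Library sizes in the sample sheet are the realized total coverage mass
    of each track. False-positive peaks (background-only) are drawn inside a
    reserved gene-free zone of each chromosome, far from planted elements.
    """
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "coverage").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([landscape.seed, 23]))
    chrom_names = [c for c, _ in landscape.genome]
    samples_out: list[SampleInfo] = []
    peak_paths: dict[str, Path] = {}
    chip_paths: dict[str, Path] = {}
    input_paths: dict[str, Path] = {}
    for s_idx, sample in enumerate(landscape.samples):
        sid = sample.sample_id
        chip_segs, input_segs, chip_mass, input_mass = _sample_coverage(landscape, sid, rng)
        peaks = [
            p
            for e in landscape.elements
            if landscape.planted_value(e, sid) > 0
            for p in e.constituents
        ]
        for f in range(landscape.false_positive_peaks):
            chrom = chrom_names[(s_idx + f) % len(chrom_names)]
            lo, hi = landscape.free_zones[chrom]
            start = int(rng.integers(lo, hi - 1_000))
            peaks.append(GenomicInterval(chrom, start, start + 1_000))
        peak_paths[sid] = out / "peaks" / f"{sid}.peaks.bed"
        write_bed(peak_paths[sid], sorted(peaks, key=lambda p: (p.chrom, p.start)))
        chip_paths[sid] = out / "coverage" / f"{sid}.chip.bedGraph"
        input_paths[sid] = out / "coverage" / f"{sid}.input.bedGraph"
        write_bedgraph(chip_paths[sid], chip_segs)
        write_bedgraph(input_paths[sid], input_segs)
        samples_out.append(
            SampleInfo(sid, sample.category, sample.subtype, chip_mass, input_mass)
        )
    metadata = out / "metadata.tsv"
    write_metadata(metadata, samples_out)
    genes_bed = out / "genes.bed"
    write_bed(genes_bed, [g.interval for g in landscape.genes])
    tss_bed = out / "tss.bed"
    write_bed(
        tss_bed,
        [
            GenomicInterval(g.interval.chrom, g.interval.start, g.interval.start + 1, g.gene_id)
            for g in landscape.genes
        ],
    )
    truth_json = out / "truth.json"
    truth_json.write_text(
        json.dumps(
            {
                "truth_labels": landscape.truth_labels,
                "elements": [
                    {
                        "element_id": e.element_id,
                        "chrom": e.interval.chrom,
                        "start": e.interval.start,
                        "end": e.interval.end,
                        "class": e.klass,
                        "cluster": e.cluster,
                        "enlarged": e.enlarged,
                        "level": e.level,
                        "gene": e.gene_id,
                        "owners": sorted(e.owners),
                    }
                    for e in landscape.elements
                ],
                "associations": landscape.associations,
                "dependencies": {g: list(v) for g, v in landscape.dependencies.items()},
                "screen_lines": landscape.screen_lines,
                "screen_normal_line": landscape.screen_normal_line,
            },
            indent=1,
        )
    )
    return StudyFiles(
        study_dir=out,
        metadata=metadata,
        peaks=peak_paths,
        chip_coverage=chip_paths,
        input_coverage=input_paths,
        genes_bed=genes_bed,
        tss_bed=tss_bed,
        truth_json=truth_json,
        samples=samples_out,
    )


# ----------------------------------------------------------------------
# expression


def simulate_expression(
    landscape: PlantedLandscape,
    noise_sd: float = 1.0,
    seed: int = 0,
    target_r: float | None = None,
) -> pd.DataFrame:
    """Gene x sample RPKM matrix with planted SE-size correlations.

    For each planted association, log2(RPKM+1) = a + b * log2(size+1) plus
    Gaussian noise whose SD is tuned (from the cell-line size variance) so
    the realized Pearson r is approximately the target; a target of 1 means
    no noise. Unassociated genes are independent noise around a fixed
    per-gene baseline with SD ``noise_sd``.
    """
    if len(landscape.sample_ids) < 6:
        raise ValueError("need >= 6 samples for meaningful correlations")
    rng = np.random.default_rng(np.random.SeedSequence([landscape.seed, int(seed), 37]))
    sizes = landscape.planted_size_matrix()
    lines = landscape.cell_lines
    assoc_by_gene = {g: (e, r) for e, g, r in landscape.associations}
    rows = {}
    a, b = 2.0, 1.0
    for gene in landscape.genes:
        if gene.gene_id in assoc_by_gene:
            element_id, r = assoc_by_gene[gene.gene_id]
            r = float(target_r) if target_r is not None else float(r)
            if not (-1.0 < r < 1.0) and r != 1.0:
                raise ValueError(f"target correlation {r} outside (-1, 1]")
            x = np.log2(sizes.loc[element_id, landscape.sample_ids].to_numpy() + 1.0)
            x_lines = np.log2(sizes.loc[element_id, lines].to_numpy() + 1.0)
            sd = 0.0 if r == 1.0 else abs(b) * x_lines.std(ddof=0) * np.sqrt(1.0 / r**2 - 1.0)
            y = a + b * x + rng.normal(0.0, sd, size=x.size)
        else:
            base = rng.uniform(1.0, 6.0)
            y = base + rng.normal(0.0, noise_sd, size=len(landscape.sample_ids))
        rows[gene.gene_id] = np.maximum(0.0, 2.0**y - 1.0)
    return pd.DataFrame(rows, index=landscape.sample_ids).T


# ----------------------------------------------------------------------
# CRISPR screen


@dataclass
class ScreenSim:
    counts: dict[str, pd.DataFrame]  # line -> (guide, gene, count_t0, count_late)
    roles: pd.Series  # gene -> target | positive_control | NTC
    guide_map: pd.DataFrame  # guide -> gene
    essential_genes: list[str]
    ntc_genes: list[str]
    target_genes: list[str]


def simulate_screen(
    landscape: PlantedLandscape,
    config: PipelineConfig | None = None,
    effect_lfc: float = -3.0,
    seed: int = 0,
    lines: list[str] | None = None,
    n_essential: int = 8,
    n_ntc: int = 8,
    dispersion: float = 30.0,
    base_mean: float = 500.0,
) -> ScreenSim:
    """Negative-binomial guide counts for a dropout screen.

    Targets are the genes associated with planted tumor-specific SEs;
    planted dependency genes deplete (by ``effect_lfc``) only in their
    dependent lines, essential positive controls deplete everywhere, NTC
    pseudo-genes never. Per-guide efficacy varies (roughly half the guides
    carry the full effect) so top-guide selection is meaningful.
    """
    config = config or PipelineConfig()
    if n_essential < 1 or n_ntc < 1:
        raise ValueError("screen needs positive-control and NTC genes")
    rng = np.random.default_rng(np.random.SeedSequence([landscape.seed, int(seed), 53]))
    lines = list(lines) if lines is not None else landscape.screen_lines + [landscape.screen_normal_line]
    targets = sorted({g for e, g, _ in landscape.associations if any(
        el.element_id == e and el.klass == "tumor_specific_SE" for el in landscape.elements
    )})
    essentials = [f"ESS{i + 1:02d}" for i in range(n_essential)]
    ntcs = [f"NTC{i + 1:02d}" for i in range(n_ntc)]
    genes = targets + essentials + ntcs
    roles = pd.Series(
        {g: "target" for g in targets}
        | {g: "positive_control" for g in essentials}
        | {g: "NTC" for g in ntcs}
    )
    gpg = config.guides_per_gene
    guide_rows = []
    efficacy = {}
    base = {}
    for gene in genes:
        n_full = max(1, gpg // 2)
        n_mid = max(0, gpg // 4)
        n_weak = gpg - n_full - n_mid
        eff = np.concatenate(
            [
                rng.uniform(0.85, 1.0, n_full),
                rng.uniform(0.4, 0.6, n_mid),
                rng.uniform(0.0, 0.15, n_weak),
            ]
        )
        rng.shuffle(eff)
        for i in range(gpg):
            guide = f"{gene}_g{i + 1}"
            guide_rows.append({"guide": guide, "gene": gene})
            efficacy[guide] = float(eff[i])
            base[guide] = float(rng.lognormal(np.log(base_mean), 0.3))
    guide_map = pd.DataFrame(guide_rows)
    counts: dict[str, pd.DataFrame] = {}
    for line in lines:
        recs = []
        for row in guide_rows:
            guide, gene = row["guide"], row["gene"]
            if gene in essentials:
                effect = effect_lfc
            elif gene in landscape.dependencies and line in landscape.dependencies[gene]:
                effect = effect_lfc
            else:
                effect = 0.0
            mu0 = base[guide]
            mu1 = mu0 * 2.0 ** (effect * efficacy[guide])
            c0 = int(rng.negative_binomial(dispersion, dispersion / (dispersion + mu0)))
            c1 = int(rng.negative_binomial(dispersion, dispersion / (dispersion + mu1)))
            recs.append(
                {"guide": guide, "gene": gene, "count_t0": c0, "count_late": c1}
            )
        counts[line] = pd.DataFrame(recs)
    return ScreenSim(
        counts=counts,
        roles=roles,
        guide_map=guide_map,
        essential_genes=essentials,
        ntc_genes=ntcs,
        target_genes=targets,
    )


def simulate_dependency_scores(
    landscape: PlantedLandscape, seed: int = 0
) -> pd.DataFrame:
    """CERES-like dependency scores (genes x cell lines).

    Planted dependency genes score around -0.9 in their dependent lines and
    around 0 elsewhere; non-dependency screen targets are neutral
    everywhere.
    """
    rng = np.random.default_rng(np.random.SeedSequence([landscape.seed, int(seed), 71]))
    lines = landscape.cell_lines
    genes = sorted({g for _, g, _ in landscape.associations})
    rows = {}
    for gene in genes:
        dep = set(landscape.dependencies.get(gene, ()))
        rows[gene] = [
            rng.normal(-0.9, 0.05) if line in dep else rng.normal(0.0, 0.05)
            for line in lines
        ]
    return pd.DataFrame(rows, index=lines).T


def write_study(
    landscape: PlantedLandscape,
    out_dir: str | Path,
    noise_sd: float = 1.0,
    effect_lfc: float = -3.0,
) -> StudyFiles:
    """Emit the complete study: sample files plus expression, screen counts
    and dependency scores, ready for the end-to-end pipeline."""
    files = emit_sample_files(landscape, out_dir)
    out = Path(out_dir)
    expr = simulate_expression(landscape, noise_sd=noise_sd)
    write_matrix(out / "expression.tsv", expr, index_label="gene_id")
    genes_df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in landscape.genes],
            "chrom": [g.interval.chrom for g in landscape.genes],
            "start": [g.interval.start for g in landscape.genes],
            "end": [g.interval.end for g in landscape.genes],
        }
    )
    genes_df.to_csv(out / "genes.tsv", sep="\t", index=False)
    screen = simulate_screen(landscape, effect_lfc=effect_lfc)
    (out / "screen").mkdir(exist_ok=True)
    for line, table in screen.counts.items():
        table.to_csv(out / "screen" / f"{line}.counts.tsv", sep="\t", index=False)
    screen.roles.rename("role").to_csv(out / "screen" / "roles.tsv", sep="\t", index_label="gene")
    ceres = simulate_dependency_scores(landscape)
    write_matrix(out / "ceres.tsv", ceres, index_label="gene")
    return files
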