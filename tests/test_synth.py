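"""The synthetic-study generator: determinism, planted invariants, coverage
construction, expression calibration and screen count behavior."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from selandscape import synth
from selandscape.genemap import pearson_log
from selandscape.io import read_bed, read_bedgraph, read_metadata
from selandscape.screen import gene_lfc, guide_lfc


def small_landscape(seed=0, **overrides):
    params = dict(
        n_line_clusters=2,
        lines_per_cluster=4,
        n_primary_clusters=1,
        primaries_per_cluster=4,
        n_outlier_lines=1,
        n_outlier_primaries=0,
        n_normals=3,
        n_shared=8,
        cs_per_cluster=2,
        n_tumor_specific=3,
        n_enlarged=1,
        n_normal_only=2,
        privates_per_outlier=2,
        n_typical=40,
        n_background_genes=10,
        seed=seed,
    )
    params.update(overrides)
    return synth.simulate_landscape(**params)


class TestDeterminism:
    def test_landscape_identical_across_runs(self):
        a, b = small_landscape(seed=7), small_landscape(seed=7)
        assert a.elements == b.elements
        assert a.samples == b.samples
        assert a.associations == b.associations
        assert a.truth_labels == b.truth_labels

    def test_emitted_files_identical_across_runs(self, tmp_path):
        land = small_landscape(seed=3)
        f1 = synth.emit_sample_files(land, tmp_path / "a")
        f2 = synth.emit_sample_files(land, tmp_path / "b")
        sid = land.sample_ids[0]
        for pair in [
            (f1.peaks[sid], f2.peaks[sid]),
            (f1.chip_coverage[sid], f2.chip_coverage[sid]),
            (f1.metadata, f2.metadata),
            (f1.truth_json, f2.truth_json),
        ]:
            assert filecmp.cmp(*pair, shallow=False)

    def test_different_seeds_differ(self, tmp_path):
        a, b = small_landscape(seed=1), small_landscape(seed=2)
        assert a.planted_size_matrix().equals(b.planted_size_matrix()) is False


class TestPlantedInvariants:
    def test_tumor_specific_ownership_satisfies_filters(self, landscape):
        lines = set(landscape.cell_lines)
        prims = set(landscape.primaries)
        normals = set(landscape.normals)
        ts = landscape.tumor_specific_elements()
        assert len(ts) == 8
        for e in ts:
            assert len(e.owners & lines) >= 4
            assert len(e.owners & prims) >= 1
            if not e.enlarged:
                assert not (e.owners & normals)
            else:
                assert e.owners >= normals

    def test_elements_within_genome_and_separated(self, landscape):
        bounds = dict(landscape.genome)
        by_chrom: dict[str, list] = {}
        for e in landscape.elements:
            assert 0 <= e.interval.start < e.interval.end <= bounds[e.interval.chrom]
            by_chrom.setdefault(e.interval.chrom, []).append(e.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert b.start - a.end > 12_500  # distinct elements never stitch

    def test_constituent_gaps_below_stitch_distance(self, landscape):
        for e in landscape.se_elements():
            cons = sorted(e.constituents, key=lambda p: p.start)
            assert cons[0].start == e.interval.start
            assert cons[-1].end == e.interval.end
            for a, b in zip(cons, cons[1:]):
                assert 0 < b.start - a.end < 12_500


class TestEmittedFiles:
    def test_files_parse_back(self, landscape, study_dir):
        samples = read_metadata(study_dir / "metadata.tsv")
        assert [s.sample_id for s in samples] == landscape.sample_ids
        sid = landscape.sample_ids[0]
        peaks = read_bed(study_dir / "peaks" / f"{sid}.peaks.bed")
        assert len(peaks) > 0
        cov = read_bedgraph(study_dir / "coverage" / f"{sid}.chip.bedGraph")
        assert cov.total_mass() == pytest.approx(samples[0].chip_library_size)

    def test_owner_enriched_over_input_nonowner_at_background(self, landscape, study_dir):
        element = next(e for e in landscape.se_elements() if e.klass == "cluster_specific_SE"
                       and e.cluster == "C1")
        owner = sorted(element.owners)[0]
        non_owner = landscape.normals[0]
        peak = element.constituents[0]
        rate = landscape.background_rate
        for sid, enriched in [(owner, True), (non_owner, False)]:
            chip = read_bedgraph(study_dir / "coverage" / f"{sid}.chip.bedGraph")
            inp = read_bedgraph(study_dir / "coverage" / f"{sid}.input.bedGraph")
            c = chip.interval_sum(peak.chrom, peak.start, peak.end)
            i = inp.interval_sum(peak.chrom, peak.start, peak.end)
            noise_sd = np.sqrt(2 * rate * peak.length)
            if enriched:
                assert c > i + 10 * noise_sd
            else:
                assert abs(c - i) < 6 * noise_sd  # both pure background

    def test_peak_bed_contains_exactly_owned_constituents_plus_fps(self, landscape, study_dir):
        sid = landscape.cell_lines[0]
        peaks = set((p.chrom, p.start, p.end) for p in
                    read_bed(study_dir / "peaks" / f"{sid}.peaks.bed"))
        owned = set(
            (p.chrom, p.start, p.end)
            for e in landscape.elements
            if landscape.planted_value(e, sid) > 0
            for p in e.constituents
        )
        assert owned <= peaks
        assert len(peaks - owned) == landscape.false_positive_peaks


class TestExpression:
    def test_noiseless_target_one_gives_exact_unit_correlation(self, landscape):
        expr = synth.simulate_expression(landscape, noise_sd=0.0, seed=0, target_r=1.0)
        sizes = landscape.planted_size_matrix()
        lines = landscape.cell_lines
        for element_id, gene_id, _ in landscape.associations:
            r = pearson_log(
                sizes.loc[element_id, lines].to_numpy(),
                expr.loc[gene_id, lines].to_numpy(),
            )
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_target_point_nine_calibration(self, landscape):
        # realized r lands in [0.7, 0.99] for >= 95% of seeds at n = 18 lines
        sizes = landscape.planted_size_matrix()
        lines = landscape.cell_lines
        element_id, gene_id, _ = landscape.associations[0]
        ok = 0
        for seed in range(200):
            expr = synth.simulate_expression(landscape, seed=seed, target_r=0.9)
            r = pearson_log(
                sizes.loc[element_id, lines].to_numpy(),
                expr.loc[gene_id, lines].to_numpy(),
            )
            ok += int(0.7 <= r <= 0.99)
        assert ok >= 190

    def test_unassociated_gene_null_correlation(self, landscape):
        sizes = landscape.planted_size_matrix()
        lines = landscape.cell_lines
        background = next(g for g in landscape.genes if g.element_id is None)
        element_id = landscape.associations[0][0]
        ok = 0
        for seed in range(100):
            expr = synth.simulate_expression(landscape, noise_sd=1.0, seed=seed)
            r = pearson_log(
                sizes.loc[element_id, lines].to_numpy(),
                expr.loc[background.gene_id, lines].to_numpy(),
            )
            ok += int(abs(r) < 0.6)
        assert ok >= 95

    def test_invalid_target_rejected(self, landscape):
        with pytest.raises(ValueError):
            synth.simulate_expression(landscape, target_r=1.5)


class TestScreenCounts:
    def test_guide_bookkeeping(self, landscape):
        sim = synth.simulate_screen(landscape, seed=0)
        n_genes = len(sim.target_genes) + len(sim.essential_genes) + len(sim.ntc_genes)
        assert len(sim.guide_map) == n_genes * 8
        for table in sim.counts.values():
            assert len(table) == n_genes * 8

    def test_null_effect_centers_lfcs(self, landscape):
        # with no planted effect, guide LFCs center on zero; gene-level raw
        # LFCs share a small common offset (the most-depleted-guides
        # selection) that is identical across roles — exactly what NTC
        # anchoring removes
        sim = synth.simulate_screen(landscape, effect_lfc=0.0, seed=1)
        table = sim.counts[landscape.screen_lines[0]]
        lfcs = guide_lfc(
            table.set_index("guide")["count_t0"], table.set_index("guide")["count_late"]
        )
        assert abs(lfcs.mean()) < 0.05
        raw = lfcs.groupby(table.set_index("guide")["gene"]).apply(gene_lfc)
        targets = raw[[g for g in sim.target_genes]].mean()
        ntc = raw[[g for g in sim.ntc_genes]].mean()
        assert abs(targets - ntc) < 0.3

    def test_essential_genes_deplete_below_ntc(self, landscape):
        for seed in range(20):
            sim = synth.simulate_screen(landscape, seed=seed)
            table = sim.counts[landscape.screen_lines[0]]
            lfcs = guide_lfc(
                table.set_index("guide")["count_t0"], table.set_index("guide")["count_late"]
            )
            raw = lfcs.groupby(table.set_index("guide")["gene"]).apply(gene_lfc)
            ess = raw[[g for g in sim.essential_genes]].mean()
            ntc = raw[[g for g in sim.ntc_genes]].mean()
            assert ess < ntc - 1.0

    def test_screen_requires_controls(self, landscape):
        with pytest.raises(ValueError):
            synth.simulate_screen(landscape, n_essential=0)


class TestNullLandscape:
    def test_zero_signal_yields_no_superenhancers(self, tmp_path):
        from selandscape import pipeline

        land = small_landscape(seed=5, signal_scale=0.0, false_positive_peaks=0)
        synth.emit_sample_files(land, tmp_path)
        study = pipeline.load_study(tmp_path)
        with pytest.warns(UserWarning):
            tables = pipeline.call_sample_enhancers(study)
        assert all(len(t.superenhancers) == 0 for t in tables.values())
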