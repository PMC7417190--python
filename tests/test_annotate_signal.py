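"""TSS annotation, signal matrices, class summaries and gene-list overlaps."""

import numpy as np
import pytest

from chromtrace.annotate_signal import (
    MatrixParams,
    TSSTable,
    annotate_nearest_tss,
    peak_gene_overlap_counts,
    regionclass_signal_summary,
    signal_matrix,
)
from chromtrace.genome_io import CoverageTrack, GenomeModel, Interval
from chromtrace.region_classes import RegionClassTable
from oracles import naive_nearest_tss


def tss_of(rows):
    return TSSTable(rows)


class TestAnnotateNearestTSS:
    def test_region_centered_on_tss(self):
        tss = tss_of([("g1", "chr1", 500, "+")])
        df = annotate_nearest_tss([Interval("chr1", 400, 600)], tss)
        assert df.loc[0, "gene"] == "g1"
        assert df.loc[0, "distance"] == 0
        assert bool(df.loc[0, "promoter_proximal"])

    def test_promoter_boundary_is_inclusive_3kb(self):
        tss = tss_of([("g1", "chr1", 0, "+")])
        at_3000 = annotate_nearest_tss([Interval("chr1", 2950, 3050)], tss)
        at_3001 = annotate_nearest_tss([Interval("chr1", 2951, 3051)], tss)
        assert bool(at_3000.loc[0, "promoter_proximal"])
        assert not bool(at_3001.loc[0, "promoter_proximal"])

    def test_matches_linear_scan_oracle(self, rng):
        rows = [
            (f"g{i:03d}", "chr1", int(p), "+")
            for i, p in enumerate(rng.integers(0, 100_000, 60))
        ]
        tss = tss_of(rows)
        regions = [Interval("chr1", int(s), int(s) + 100)
                   for s in rng.integers(0, 99_900, 200)]
        df = annotate_nearest_tss(regions, tss)
        for r, (_, row) in zip(regions, df.iterrows()):
            gene, signed = naive_nearest_tss(r, rows)
            assert row["gene"] == gene
            assert row["distance"] == signed

    def test_tie_broken_by_gene_name(self):
        tss = tss_of([("zeta", "chr1", 100, "+"), ("alpha", "chr1", 300, "-")])
        df = annotate_nearest_tss([Interval("chr1", 150, 250)], tss)  # center 200
        assert df.loc[0, "gene"] == "alpha"

    def test_chromosome_without_tss_warns_unannotated(self):
        tss = tss_of([("g1", "chr1", 100, "+")])
        with pytest.warns(UserWarning, match="without any TSS"):
            df = annotate_nearest_tss([Interval("chr9", 0, 100)], tss)
        assert df.loc[0, "gene"] is None

    def test_duplicate_gene_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            tss_of([("g", "chr1", 1, "+"), ("g", "chr1", 5, "+")])


class TestSignalMatrix:
    def constant_track(self, value=3.0, L=20_000):
        g = GenomeModel({"chr1": L})
        return CoverageTrack({"chr1": np.full(L, value)}, g.chrom_lengths, tag="RPM")

    def test_constant_track_fills_every_cell(self):
        track = self.constant_track(3.0)
        mat = signal_matrix(track, [Interval("chr1", 9000, 9600)],
                            MatrixParams(flank=2000, bin=10))
        assert mat.matrices[0].shape == (1, 400)  # 4 kb window, 10 bp bins
        np.testing.assert_allclose(mat.matrices[0], 3.0)
        np.testing.assert_allclose(mat.profile(), 3.0)

    def test_rows_sorted_by_first_sample_order(self, rng):
        g = GenomeModel({"chr1": 50_000})
        t1 = CoverageTrack({"chr1": rng.random(50_000)}, g.chrom_lengths, tag="RPM")
        t2 = CoverageTrack({"chr1": rng.random(50_000)}, g.chrom_lengths, tag="RPM")
        regions = [Interval("chr1", int(s), int(s) + 300)
                   for s in rng.integers(3000, 45_000, 25)]
        params = MatrixParams(flank=1000, bin=10)
        mat = signal_matrix([t1, t2], regions, params)
        # independent sort oracle on the first sample
        means = []
        for r in regions:
            w = t1.data["chr1"][r.center - 1000 : r.center + 1000]
            means.append(w.reshape(-1, 10).mean(axis=1).mean())
        expected_order = np.argsort(-np.asarray(means), kind="stable")
        np.testing.assert_array_equal(mat.row_order, expected_order)
        # second sample rows follow the first sample's order
        np.testing.assert_allclose(
            mat.matrices[1][0],
            t2.data["chr1"][
                regions[expected_order[0]].center - 1000 :
                regions[expected_order[0]].center + 1000
            ].reshape(-1, 10).mean(axis=1),
        )

    def test_off_chromosome_bins_are_nan_and_excluded(self):
        track = self.constant_track(2.0, L=3000)
        mat = signal_matrix(track, [Interval("chr1", 0, 200)],
                            MatrixParams(flank=2000, bin=10))
        row = mat.matrices[0][0]
        assert np.isnan(row[:190]).all()       # window extends before base 0
        assert np.isfinite(row[200:]).all()
        np.testing.assert_allclose(mat.profile()[200:], 2.0)

    def test_mass_conservation(self, rng):
        g = GenomeModel({"chr1": 30_000})
        track = CoverageTrack({"chr1": rng.random(30_000)}, g.chrom_lengths, tag="RPM")
        r = Interval("chr1", 10_000, 10_300)
        mat = signal_matrix(track, [r], MatrixParams(flank=1000, bin=10))
        window_sum = track.data["chr1"][r.center - 1000 : r.center + 1000].sum()
        assert mat.matrices[0].sum() * 10 == pytest.approx(window_sum)


class TestRegionClassSummary:
    def test_zero_track_gives_zero_summaries(self):
        g = GenomeModel({"chr1": 10_000})
        track = CoverageTrack.zeros(g, tag="RPM")
        table = RegionClassTable([Interval("chr1", 1000, 1600)], ["A_only"])
        s = regionclass_signal_summary(track, table)
        assert s.loc[0, "mean"] == 0.0

    def test_single_region_class_equals_its_value(self):
        g = GenomeModel({"chr1": 10_000})
        arr = np.zeros(10_000)
        arr[800:1800] = 5.0  # exactly the 1 kb window around center 1300
        track = CoverageTrack({"chr1": arr}, g.chrom_lengths, tag="RPM")
        table = RegionClassTable([Interval("chr1", 1000, 1600)], ["AB_overlap"])
        s = regionclass_signal_summary(track, table, bin=1000)
        assert s.loc[0, "mean"] == pytest.approx(5.0)

    def test_twofold_weight_gives_twofold_summary(self, rng):
        g = GenomeModel({"chr1": 60_000})
        arr = np.zeros(60_000)
        regions, labels = [], []
        for i in range(30):
            s = 1000 + i * 2000
            weight = 2.0 if i % 3 == 0 else 1.0
            arr[s : s + 1000] = 10.0 * weight
            regions.append(Interval("chr1", s, s + 1000))
            labels.append("AB_overlap" if i % 3 == 0 else ("A_only" if i % 3 == 1 else "B_only"))
        track = CoverageTrack({"chr1": arr}, g.chrom_lengths, tag="RPM")
        table = RegionClassTable(regions, labels)
        s = regionclass_signal_summary(track, table).set_index("label")
        ratio = s.loc["AB_overlap", "mean"] / s.loc["A_only", "mean"]
        assert 1.6 <= ratio <= 2.4

    def test_invariant_to_region_order(self, rng):
        g = GenomeModel({"chr1": 30_000})
        track = CoverageTrack({"chr1": rng.random(30_000)}, g.chrom_lengths, tag="RPM")
        regions = [Interval("chr1", int(s), int(s) + 400)
                   for s in rng.integers(1000, 28_000, 12)]
        labels = ["A_only", "B_only", "AB_overlap"] * 4
        fwd = regionclass_signal_summary(track, RegionClassTable(regions, labels))
        rev = regionclass_signal_summary(
            track, RegionClassTable(regions[::-1], labels[::-1])
        )
        assert fwd.sort_values("label").reset_index(drop=True).equals(
            rev.sort_values("label").reset_index(drop=True)
        )


class TestPeakGeneOverlap:
    def grid_tss(self, n=100):
        return TSSTable([(f"g{i:03d}", "chr1", 1000 + i * 2000, "+") for i in range(n)])

    def test_all_genes_list_counts_distinct_associated(self):
        tss = self.grid_tss(20)
        regions = [Interval("chr1", 900 + i * 2000, 1100 + i * 2000) for i in range(5)]
        df = peak_gene_overlap_counts(
            regions, tss, {"all": [f"g{i:03d}" for i in range(20)]}
        )
        assert df.loc[0, "overlap_count"] == 5

    def test_disjoint_namespace_counts_zero_with_tally(self):
        tss = self.grid_tss(10)
        regions = [Interval("chr1", 900, 1100)]
        df = peak_gene_overlap_counts(regions, tss, {"other": ["x1", "x2"]})
        assert df.loc[0, "overlap_count"] == 0
        assert df.loc[0, "namespace_mismatches"] == 2

    def test_planted_peaks_at_down_gene_tss(self):
        tss = self.grid_tss(100)
        down = [f"g{i:03d}" for i in range(100)][:40]
        regions = [Interval("chr1", 900 + i * 2000, 1100 + i * 2000) for i in range(40)]
        df = peak_gene_overlap_counts(regions, tss, {"down": down})
        assert df.loc[0, "overlap_count"] == 40
        assert df.loc[0, "fraction"] == pytest.approx(1.0)

    def test_empty_gene_list_warns(self):
        tss = self.grid_tss(5)
        with pytest.warns(UserWarning, match="empty"):
            df = peak_gene_overlap_counts([Interval("chr1", 900, 1100)], tss, {"e": []})
        assert df.loc[0, "overlap_count"] == 0
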