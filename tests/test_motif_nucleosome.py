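"""Motif scanning, mutation audit, dyad calling and distance distributions."""

import numpy as np
import pytest

from chromtrace.genome_io import FragmentSet, GenomeModel, Interval
from chromtrace.motif_nucleosome import (
    ENHANCER_SITE_PAIRS,
    DistanceDistribution,
    DyadCallParams,
    DyadSet,
    MotifMatch,
    MotifMatchSet,
    MotifModel,
    call_dyads,
    distribution_shift_test,
    motif_dyad_distances,
    partition_bound,
    scan_motif,
    site_mutation_audit,
)
from chromtrace.synthetic_data import (
    SimConfig,
    reverse_complement,
    simulate_atac,
    simulate_genome,
)
from oracles import naive_scan

CONS = "caacgcccgcca"


def genome_with(seq: str) -> GenomeModel:
    return GenomeModel({"chr1": len(seq)}, {"chr1": seq})


class TestSiteMutationAudit:
    def test_printed_enhancer_pairs(self):
        dists = site_mutation_audit(ENHANCER_SITE_PAIRS)
        assert dists == [3, 2, 3, 2, 4]
        assert all(2 <= d <= 4 for d in dists)

    def test_identical_pair_is_zero(self):
        assert site_mutation_audit([("acgt", "ACGT")]) == [0]

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="length mismatch"):
            site_mutation_audit([("acgt", "acg")])


class TestScanMotif:
    def test_exact_consensus_window_matches(self):
        g = genome_with("tttt" + CONS + "tttt")
        matches = scan_motif(g, MotifModel(consensus=CONS, max_mismatch=1))
        exact = [m for m in matches if m.score == 0]
        assert len(exact) == 1
        assert (exact[0].start, exact[0].strand) == (4, "+")

    def test_two_mismatches_not_matched_at_budget_one(self):
        g = genome_with("tttt" + "caacgcATgcca".upper() + "tttt")
        matches = scan_motif(g, MotifModel(consensus=CONS, max_mismatch=1))
        assert all(m.start != 4 for m in matches)

    def test_reverse_complement_found_on_minus_strand(self):
        g = genome_with("tttt" + reverse_complement(CONS) + "tttt")
        matches = scan_motif(g, MotifModel(consensus=CONS, max_mismatch=0))
        assert len(matches) == 1
        assert matches[0].strand == "-"

    def test_n_windows_skipped_and_tallied(self):
        g = genome_with("tttt" + CONS[:6] + "N" + CONS[7:] + "tttt")
        matches = scan_motif(g, MotifModel(consensus=CONS, max_mismatch=2))
        assert all(not (m.start <= 10 < m.end) for m in matches)
        # 20 bp sequence, 12 bp motif: 9 windows, every one crosses the N
        assert matches.n_skipped_windows == 9

    def test_equals_naive_exhaustive_scan(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        # plant a few exact and near-miss copies on both strands
        seq = seq[:1000] + CONS.upper() + seq[1012:5000] + \
            reverse_complement(CONS).upper() + seq[5012:]
        g = genome_with(seq)
        got = scan_motif(g, MotifModel(consensus=CONS, max_mismatch=1))
        expected = naive_scan(g.sequence, CONS, 1)
        assert [(m.chrom, m.start, m.strand, m.score) for m in got] == [
            (c, s, st, float(mm)) for c, s, st, mm in expected
        ]

    def test_pwm_mode_agrees_with_exact_consensus(self):
        seq = "tttt" + CONS + "tttttttt" + reverse_complement(CONS) + "tttt"
        g = genome_with(seq)
        one_hot = np.zeros((len(CONS), 4))
        for i, b in enumerate(CONS.upper()):
            one_hot[i, "ACGT".index(b)] = 100.0
        model = MotifModel(pwm=one_hot, score_threshold=0.0)
        lo = model.log_odds()
        threshold = lo.max(axis=1).sum() - 1e-9  # only perfect windows
        pwm_hits = scan_motif(g, MotifModel(pwm=one_hot, score_threshold=threshold))
        cons_hits = scan_motif(g, MotifModel(consensus=CONS, max_mismatch=0))
        assert [(m.start, m.strand) for m in pwm_hits] == [
            (m.start, m.strand) for m in cons_hits
        ]

    def test_width_and_mismatch_validation(self):
        with pytest.raises(ValueError):
            MotifModel(consensus="acg")
        with pytest.raises(ValueError):
            MotifModel(consensus="acgtacgt", max_mismatch=8)


class TestPartitionBound:
    def test_whole_genome_peak_binds_everything(self, default_sim):
        _, genome, truth = default_sim
        matches = scan_motif(genome, MotifModel(consensus=truth.motif, max_mismatch=1))
        covered = partition_bound(
            matches, [Interval(c, 0, genome.length(c)) for c in genome.chrom_names]
        )
        assert covered.counts()["bound"] == len(matches)

    def test_empty_peak_set_binds_nothing(self, default_sim):
        _, genome, truth = default_sim
        matches = scan_motif(genome, MotifModel(consensus=truth.motif, max_mismatch=1))
        free = partition_bound(matches, [])
        c = free.counts()
        assert c["bound"] == 0 and c["unbound"] == c["total"]

    def test_partition_counts_sum_to_total(self, default_sim):
        _, genome, truth = default_sim
        matches = scan_motif(genome, MotifModel(consensus=truth.motif, max_mismatch=1))
        part = partition_bound(matches, truth.bound_sites("A"))
        c = part.counts()
        assert c["bound"] + c["unbound"] == c["total"]

    def test_truth_channel_agreement(self, default_sim):
        # flags against the true bound-site intervals match site planting exactly
        _, genome, truth = default_sim
        matches = scan_motif(genome, MotifModel(consensus=truth.motif, max_mismatch=0))
        part = partition_bound(matches, truth.bound_sites("A"))
        site_keys = {(s.chrom, s.start) for s in truth.bound_sites("A")}
        agree = sum(
            ((m.chrom, m.start) in site_keys) == m.bound for m in part
        )
        assert agree / len(part) >= 0.95


class TestCallDyads:
    def test_single_fragment_dyad_at_midpoint(self):
        frags = FragmentSet([Interval("chr1", 1000, 1147)])
        dyads = call_dyads(frags, [Interval("chr1", 900, 1300)], DyadCallParams(),
                           {"chr1": 2000})
        assert list(dyads.positions("chr1")) == [1073]

    def test_two_clusters_recovered_within_tolerance(self, rng):
        frags = []
        for center in (2000, 2300):
            mids = rng.normal(center, 20, 200)
            lens = rng.integers(120, 201, 200)
            frags += [
                Interval("chr1", int(m - l // 2), int(m - l // 2) + int(l))
                for m, l in zip(mids, lens)
            ]
        dyads = call_dyads(FragmentSet(frags), [Interval("chr1", 1500, 2800)],
                           DyadCallParams(), {"chr1": 5000})
        pos = dyads.positions("chr1")
        assert len(pos) == 2
        assert abs(pos[0] - 2000) <= 20 and abs(pos[1] - 2300) <= 20

    def test_close_clusters_thinned_to_one(self, rng):
        frags = []
        for center in (2000, 2060):
            mids = rng.normal(center, 15, 200)
            lens = rng.integers(120, 201, 200)
            frags += [
                Interval("chr1", int(m - l // 2), int(m - l // 2) + int(l))
                for m, l in zip(mids, lens)
            ]
        dyads = call_dyads(FragmentSet(frags), [Interval("chr1", 1500, 2500)],
                           DyadCallParams(min_separation=120), {"chr1": 5000})
        assert len(dyads.positions("chr1")) == 1

    def test_no_fragments_in_band_is_an_error(self):
        frags = FragmentSet([Interval("chr1", 0, 80)])  # sub-nucleosomal only
        with pytest.raises(ValueError, match="no fragments"):
            call_dyads(frags, [Interval("chr1", 0, 1000)], DyadCallParams(),
                       {"chr1": 1000})

    def test_regions_without_dyads_dropped(self, rng):
        mids = rng.normal(2000, 20, 100)
        frags = FragmentSet([
            Interval("chr1", int(m) - 73, int(m) + 74) for m in mids
        ])
        regions = [Interval("chr1", 1500, 2500), Interval("chr1", 8000, 9000)]
        dyads = call_dyads(frags, regions, DyadCallParams(), {"chr1": 10_000})
        assert dyads.regions == [Interval("chr1", 1500, 2500)]

    def test_recovery_and_separation_on_simulated_sample(self):
        cfg = SimConfig(seed=19, nfr_fraction=0.2, nuc_fraction=0.6, atac_depth=83_000)
        genome, truth = simulate_genome(cfg)
        frags = simulate_atac(genome, truth, cfg, "wt")
        regions = [Interval(s.chrom, s.center - 450, s.center + 450)
                   for s in truth.all_sites()]
        params = DyadCallParams()
        called = call_dyads(frags, regions, params, genome.chrom_lengths)
        hits = total = 0
        for chrom, arr in truth.true_dyads["wt"].items():
            pos = called.positions(chrom)
            for t in arr:
                total += 1
                i = np.searchsorted(pos, t)
                near = [abs(int(t) - int(pos[j])) for j in (i - 1, i)
                        if 0 <= j < pos.size]
                hits += bool(near) and min(near) <= 20
        assert hits / total >= 0.90
        for pos in called.dyads.values():
            assert np.all(np.diff(pos) >= params.min_separation)


class TestDistances:
    def make_matches(self, centers, bound):
        return MotifMatchSet([
            MotifMatch("chr1", c - 6, c + 6, "+", 0.0, bound=b)
            for c, b in zip(centers, bound)
        ])

    def dyad_set(self, positions, regions=()):
        pos = np.sort(np.asarray(positions, dtype=np.int64))
        return DyadSet({"chr1": pos}, {"chr1": np.ones(pos.size)}, list(regions))

    def test_motif_on_dyad_gives_zero(self):
        matches = self.make_matches([1000], [True])
        dd = motif_dyad_distances(matches, self.dyad_set([1000]),
                                  restrict_to_regions=False)
        assert dd["bound"].distances.tolist() == [0.0]

    def test_nearest_rule(self):
        matches = self.make_matches([1150], [True])
        dd = motif_dyad_distances(matches, self.dyad_set([1000, 1400]),
                                  restrict_to_regions=False)
        assert dd["bound"].distances.tolist() == [150.0]

    def test_empty_category_omitted_with_warning(self):
        matches = self.make_matches([1000], [True])
        with pytest.warns(UserWarning, match="unbound"):
            dd = motif_dyad_distances(matches, self.dyad_set([900]),
                                      restrict_to_regions=False)
        assert "unbound" not in dd

    def test_restriction_to_retained_regions(self):
        matches = self.make_matches([1000, 5000], [True, True])
        dyads = self.dyad_set([950], regions=[Interval("chr1", 900, 1100)])
        dd = motif_dyad_distances(matches, dyads)
        assert dd["bound"].n == 1  # the match at 5000 is outside analysis regions

    def test_ecdf_monotone_to_one(self, rng):
        d = DistanceDistribution(rng.integers(0, 500, 100), "bound")
        xs = np.arange(0, 600, 10)
        e = d.ecdf(xs)
        assert np.all(np.diff(e) >= 0)
        assert e[-1] == 1.0
        assert 0.0 <= d.frac_within_half_nucleosome <= 1.0


class TestShiftTest:
    def test_identical_distributions(self):
        a = DistanceDistribution(np.arange(100), "bound")
        b = DistanceDistribution(np.arange(100), "bound")
        ks, p, med = distribution_shift_test(a, b)
        assert ks == 0.0 and med == 0.0

    def test_constant_shift_detected(self, rng):
        base = rng.integers(0, 300, 300)
        a = DistanceDistribution(base, "bound", "wt")
        b = DistanceDistribution(base + 100, "bound", "shifted")
        ks, p, med = distribution_shift_test(a, b)
        assert med == 100.0
        assert p < 0.01

    def test_null_is_calibrated(self, rng):
        # same-distribution samples: p should rarely be extreme
        ps = []
        for _ in range(20):
            a = DistanceDistribution(rng.integers(0, 300, 150), "bound")
            b = DistanceDistribution(rng.integers(0, 300, 150), "bound")
            ps.append(distribution_shift_test(a, b)[1])
        assert min(ps) > 1e-4
        assert max(ps) > 0.2
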