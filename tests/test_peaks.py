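"""Peak calling against brute-force oracles, blacklist/broad/differential logic."""

import numpy as np
import pytest
from scipy import stats

from chromtrace.genome_io import FragmentSet, GenomeModel, Interval
from chromtrace.peaks import (
    DifferentialParams,
    PeakCallParams,
    PeakSet,
    broaden,
    call_peaks,
    differential_peaks,
    remove_blacklisted,
)
from chromtrace.synthetic_data import SimConfig, simulate_chip, simulate_genome
from oracles import naive_call_peaks


def small_chip_case(seed=1):
    cfg = SimConfig(seed=seed, n_chroms=1, chrom_length=30_000, n_sites_A=5,
                    n_sites_B=0, n_sites_shared=0, n_unbound_sites=0)
    genome, truth = simulate_genome(cfg)
    signal = simulate_chip(genome, truth, cfg, "A")
    control = simulate_chip(genome, truth, cfg, "input")
    return genome, truth, signal, control


class TestCallPeaks:
    def test_empty_signal_is_an_error(self):
        g = GenomeModel({"chr1": 10_000})
        with pytest.raises(ValueError, match="empty"):
            call_peaks(FragmentSet([]), None, g, PeakCallParams())

    def test_zero_depth_background_is_an_error(self):
        g = GenomeModel({"chr1": 10_000})
        sig = FragmentSet([Interval("chr1", 0, 100)])
        with pytest.raises(ValueError, match="zero depth"):
            call_peaks(sig, FragmentSet([]), g, PeakCallParams())

    def test_uniform_signal_yields_no_peaks(self, rng):
        g = GenomeModel({"chr1": 50_000})
        starts = rng.integers(0, 49_800, 2000)
        sig = FragmentSet([Interval("chr1", int(s), int(s) + 200) for s in starts])
        ps = call_peaks(sig, None, g, PeakCallParams(q_threshold=1e-5))
        assert len(ps) == 0

    def test_single_enriched_region_poisson_oracle(self, rng):
        g = GenomeModel({"chr1": 50_000})
        frags = [Interval("chr1", int(s), int(s) + 200)
                 for s in rng.integers(0, 49_800, 500)]
        frags += [Interval("chr1", 24_900, 25_100)] * 60
        sig = FragmentSet(frags)
        # min_dist = window so overlapping windows over one pileup collapse
        params = PeakCallParams.chip(min_dist=200)
        ps = call_peaks(sig, None, g, params)
        hits = [p for p in ps if p.start <= 25_000 < p.end]
        assert len(hits) == 1
        # the reported p equals a direct Poisson tail at the reported lambda
        peak = hits[0]
        mids = np.sort([(f.start + f.end) // 2 for f in frags])
        k = np.searchsorted(mids, peak.end) - np.searchsorted(mids, peak.start)
        assert peak.count == k
        lam = k / peak.fold
        assert peak.p == pytest.approx(float(stats.poisson.sf(k - 1, lam)))

    def test_greedy_suppression_of_nearby_sites(self):
        # two strong clusters 40 bp apart on a 1 kb toy genome -> one peak
        g = GenomeModel({"chr1": 1000})
        frags = [Interval("chr1", 425, 575)] * 40 + [Interval("chr1", 465, 615)] * 40
        frags += [Interval("chr1", int(s), int(s) + 150)
                  for s in np.linspace(0, 840, 20).astype(int)]
        ps = call_peaks(FragmentSet(frags), None, g,
                        PeakCallParams(window=150, min_dist=50, q_threshold=1e-5))
        assert len(ps) == 1
        assert ps.peaks[0].start <= 500 and 540 < ps.peaks[0].end

    def test_oracle_equivalence_on_small_genome(self):
        genome, _, signal, control = small_chip_case()
        params = PeakCallParams.chip()
        got = call_peaks(signal, control, genome, params)
        expected = naive_call_peaks(signal, control, genome, params)
        assert [(p.chrom, p.start, p.end, p.count) for p in got] == expected

    def test_lowering_q_threshold_never_adds_peaks(self):
        genome, _, signal, control = small_chip_case()
        loose = call_peaks(signal, control, genome,
                           PeakCallParams.chip(q_threshold=1e-3))
        strict = call_peaks(signal, control, genome,
                            PeakCallParams.chip(q_threshold=1e-8))
        loose_set = {(p.chrom, p.start) for p in loose}
        assert {(p.chrom, p.start) for p in strict} <= loose_set

    def test_min_dist_honored(self):
        genome, _, signal, control = small_chip_case()
        ps = call_peaks(signal, control, genome, PeakCallParams.chip(min_dist=250))
        centers = sorted(p.center for p in ps)
        assert all(b - a >= 250 for a, b in zip(centers, centers[1:]))


class TestBlacklist:
    def make(self, ivs):
        from chromtrace.peaks import Peak

        return PeakSet([Peak(i.chrom, i.start, i.end, 1, 1.0, 0.5, 0.5) for i in ivs])

    def test_empty_blacklist_is_identity(self):
        ps = self.make([Interval("chr1", 0, 100)])
        assert len(remove_blacklisted(ps, [])) == 1

    def test_single_bp_overlap_drops_peak(self):
        ps = self.make([Interval("chr1", 100, 250)])
        assert len(remove_blacklisted(ps, [Interval("chr1", 249, 300)])) == 0
        assert len(remove_blacklisted(ps, [Interval("chr1", 250, 300)])) == 1

    def test_matches_quadratic_oracle(self, rng):
        peaks_iv = [Interval("chr1", int(s), int(s) + 100)
                    for s in rng.integers(0, 9900, 50)]
        blk = [Interval("chr1", int(s), int(s) + 80)
               for s in rng.integers(0, 9900, 30)]
        ps = self.make(peaks_iv)
        got = {(p.chrom, p.start) for p in remove_blacklisted(ps, blk)}
        expected = {
            (p.chrom, p.start)
            for p in peaks_iv
            if not any(p.overlaps(b) for b in blk)
        }
        assert got == expected


class TestBroaden:
    def test_zero_flank_on_disjoint_peaks_is_identity(self):
        ivs = [Interval("c", 100, 200), Interval("c", 400, 500)]
        assert broaden(ivs, 0) == ivs

    def test_flank_extension_and_merge(self):
        ivs = [Interval("c", 400, 550), Interval("c", 700, 850)]
        assert broaden(ivs, 200) == [Interval("c", 200, 1050)]

    def test_clipped_at_chromosome_start_and_end(self):
        g = GenomeModel({"c": 900})
        assert broaden([Interval("c", 50, 150), Interval("c", 800, 880)], 200, g) == [
            Interval("c", 0, 350),
            Interval("c", 600, 900),
        ]


class TestDifferential:
    def uniform(self, rng, n, L=10_000):
        return FragmentSet([Interval("chr1", int(s), int(s) + 80)
                            for s in rng.integers(0, L - 80, n)])

    def test_identical_samples_yield_nothing(self, rng):
        fs = self.uniform(rng, 2000)
        cands = [Interval("chr1", 1000, 1400), Interval("chr1", 5000, 5400)]
        assert len(differential_peaks(fs, fs, cands, DifferentialParams())) == 0

    def test_fourfold_drop_called_closed(self, rng):
        # control has a dense region; target drops it 4x
        base = [Interval("chr1", int(s), int(s) + 80)
                for s in rng.integers(0, 9920, 1000)]
        control = FragmentSet(
            base + [Interval("chr1", int(s), int(s) + 80)
                    for s in rng.integers(2000, 2320, 400)]
        )
        target = FragmentSet(
            base + [Interval("chr1", int(s), int(s) + 80)
                    for s in rng.integers(2000, 2320, 100)]
        )
        diff = differential_peaks(target, control, [Interval("chr1", 1900, 2500)],
                                  DifferentialParams(min_fold=2))
        assert len(diff.closed_in_target()) == 1

    def test_mild_drop_below_fold_gate_not_called(self, rng):
        base = [Interval("chr1", int(s), int(s) + 80)
                for s in rng.integers(0, 9920, 1000)]
        control = FragmentSet(
            base + [Interval("chr1", int(s), int(s) + 80)
                    for s in rng.integers(2000, 2320, 300)]
        )
        target = FragmentSet(
            base + [Interval("chr1", int(s), int(s) + 80)
                    for s in rng.integers(2000, 2320, 200)]
        )
        diff = differential_peaks(target, control, [Interval("chr1", 1900, 2500)],
                                  DifferentialParams(min_fold=2))
        assert len(diff.closed_in_target()) == 0

    def test_raising_min_fold_never_adds_calls(self, rng):
        base = [Interval("chr1", int(s), int(s) + 80)
                for s in rng.integers(0, 9920, 800)]
        control = FragmentSet(
            base + [Interval("chr1", int(s), int(s) + 80)
                    for s in rng.integers(2000, 2320, 400)]
        )
        target = FragmentSet(base)
        cands = [Interval("chr1", 1900, 2500), Interval("chr1", 6000, 6600)]
        loose = differential_peaks(target, control, cands, DifferentialParams(min_fold=2))
        strict = differential_peaks(target, control, cands, DifferentialParams(min_fold=4))
        assert {(p.chrom, p.start) for p in strict} <= {(p.chrom, p.start) for p in loose}

    def test_empty_inputs_are_errors(self):
        with pytest.raises(ValueError):
            differential_peaks(FragmentSet([]), FragmentSet([Interval("c", 0, 10)]),
                               [], DifferentialParams())
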