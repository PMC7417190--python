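"""Fixed-condition benchmark studies over the synthetic-data generator.

Each study simulates one experiment at declared conditions, runs the relevant
pipeline stage(s), scores the result against the generator's ground truth, and
returns a flat metric dict. The analysis drivers, the test suite and the
reproduction script all call these functions, so the numbers they report are
always recomputed from scratch.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np

from . import atac_norm, motif_nucleosome, peaks, pipeline
from .genome_io import Interval, coverage_from_fragments
from .region_classes import RegionClassTable
from .synthetic_data import (
    SimConfig,
    simulate_atac,
    simulate_chip,
    simulate_genome,
    simulate_track,
)


def peak_recovery_study(seed: int = 1) -> dict[str, Any]:
    """Recovery of 200 planted bound sites by the ChIP peak caller.

    Conditions: 10 x 100 kb chromosomes, 8-fold enrichment at sites,
    5000 background fragments per 100 kb, peaks called against a matched
    input sample; a peak recovers a site when its center lies within
    window/2 of the site center.
    """
    cfg = SimConfig(
        seed=seed, n_chroms=10, chrom_length=100_000,
        n_sites_A=120, n_sites_B=0, n_sites_shared=80, n_unbound_sites=0,
        chip_enrichment=8.0, chip_depth_per_100kb=5000,
    )
    genome, truth = simulate_genome(cfg)
    signal = simulate_chip(genome, truth, cfg, "A")
    control = simulate_chip(genome, truth, cfg, "input")
    params = peaks.PeakCallParams.chip()
    ps = peaks.call_peaks(signal, control, genome, params, sample_label="chip_A")
    sites = truth.bound_sites("A")
    sens, prec = pipeline.center_recovery(ps.intervals(), sites, params.window // 2)
    return {
        "sensitivity": sens, "precision": prec,
        "n_sites": len(sites), "n_peaks": len(ps),
    }


def normalization_study(seed: int = 1) -> dict[str, Any]:
    """Background-model self-consistency on a log-normal-by-construction track.

    A 1 Mb genome carries 10 accessible regions over a background whose per-bp
    RPM is log-normal with log2-mean 3 and log2-SD 0.5. The study fits the
    background model (100000 random 150 bp regions) and then normalizes the
    same track, reporting the recovered (mu, sigma) and the z mean/SD over
    freshly sampled background bases.
    """
    mu_true, sigma_true = 3.0, 0.5
    cfg = SimConfig(
        seed=seed, n_chroms=1, chrom_length=1_000_000,
        n_sites_A=10, n_sites_B=0, n_sites_shared=0, n_unbound_sites=0,
        background_lognormal=(mu_true, sigma_true), signal_amplitude=200.0,
    )
    genome, truth = simulate_genome(cfg)
    track = simulate_track(genome, truth, cfg)
    params = atac_norm.NormalizationParams(seed=seed)
    zones = atac_norm.define_background_zones(track, genome, params)
    model = atac_norm.sample_background(track, zones, params, genome)
    norm = atac_norm.normalize_track(track, model, params)
    z_mean, z_sd = pipeline.background_z_stats(
        norm, zones, params, genome.chrom_lengths
    )
    return {
        "mu": model.mu, "sigma": model.sigma,
        "mu_true": mu_true, "sigma_true": sigma_true,
        "mu_abs_error": abs(model.mu - mu_true),
        "sigma_abs_error": abs(model.sigma - sigma_true),
        "z_mean": z_mean, "z_sd": z_sd,
        "n_scores": model.n_scores, "n_regions_kept": model.n_regions_kept,
    }


def _site_windows(truth, half: int = 450) -> list[Interval]:
    """Analysis windows around every planted site (covers its dyad array)."""
    return [
        Interval(s.chrom, s.center - half, s.center + half)
        for s in truth.all_sites()
    ]


def dyad_recovery_study(seed: int = 1) -> dict[str, Any]:
    """Dyad-caller recovery at ~200 nucleosomal fragments per true dyad.

    Default 2 x 100 kb genome (62 sites, 248 true dyads); nucleosomal
    fragments have lengths in [120, 200] and midpoints jittered 20 bp SD
    around the dyads. Recovery = fraction of true dyads with a called dyad
    within +/-20 bp; separation violations are counted over all reported dyads.
    """
    cfg = SimConfig(seed=seed, nfr_fraction=0.2, nuc_fraction=0.6, atac_depth=83_000)
    genome, truth = simulate_genome(cfg)
    frags = simulate_atac(genome, truth, cfg, "wt")
    params = motif_nucleosome.DyadCallParams()
    called = motif_nucleosome.call_dyads(
        frags, _site_windows(truth), params, genome.chrom_lengths
    )
    recovery = pipeline.dyad_recovery(called, truth.true_dyads["wt"], tol=20)
    violations = 0
    for chrom, pos in called.dyads.items():
        if pos.size > 1:
            violations += int(np.sum(np.diff(pos) < params.min_separation))
    n_true = sum(a.size for a in truth.true_dyads["wt"].values())
    return {
        "recovery": recovery,
        "separation_violations": violations,
        "n_true_dyads": int(n_true),
        "n_called_dyads": called.n_dyads(),
        "fragments_per_dyad": cfg.atac_depth * cfg.nuc_fraction / n_true,
    }


def displacement_study(seed: int = 1, delta: int = 80) -> dict[str, Any]:
    """Nucleosome-displacement detection at bound motifs (ECDF shift analysis).

    200 bound sites (A + shared) over 10 x 100 kb chromosomes; under the
    overexpression condition the dyads flanking bound sites shift outward by
    ``delta`` bp. Motif matches are partitioned bound/unbound against called
    ChIP peaks; motif-to-nearest-dyad distances are compared between wild type
    and overexpression per category with a two-sample KS test.
    """
    cfg = SimConfig(
        seed=seed, n_chroms=10, chrom_length=100_000,
        n_sites_A=120, n_sites_B=120, n_sites_shared=80, n_unbound_sites=40,
        nfr_fraction=0.2, nuc_fraction=0.6, atac_depth=240_000,
        displacement_delta=delta,
    )
    genome, truth = simulate_genome(cfg)
    chip = simulate_chip(genome, truth, cfg, "A")
    chip_input = simulate_chip(genome, truth, cfg, "input")
    chip_peaks = peaks.call_peaks(
        chip, chip_input, genome, peaks.PeakCallParams.chip(), sample_label="chip_A"
    )
    motif = motif_nucleosome.MotifModel(consensus=truth.motif, max_mismatch=1)
    matches = motif_nucleosome.scan_motif(genome, motif)
    matches = motif_nucleosome.partition_bound(matches, chip_peaks)
    regions = _site_windows(truth)
    dyad_params = motif_nucleosome.DyadCallParams()
    out: dict[str, Any] = {"delta": delta}
    dists = {}
    for cond in ("wt", "overexpress_A"):
        frags = simulate_atac(genome, truth, cfg, cond)
        dyads = motif_nucleosome.call_dyads(
            frags, regions, dyad_params, genome.chrom_lengths
        )
        dists[cond] = motif_nucleosome.motif_dyad_distances(
            matches, dyads, condition=cond
        )
    for cat in ("bound", "unbound"):
        ks, p, med = motif_nucleosome.distribution_shift_test(
            dists["wt"][cat], dists["overexpress_A"][cat]
        )
        out[f"{cat}_median_shift"] = med
        out[f"{cat}_ks"] = ks
        out[f"{cat}_p"] = p
        out[f"n_{cat}"] = dists["wt"][cat].n
    return out


def differential_study(seed: int = 1) -> dict[str, Any]:
    """Differential-accessibility calls under a 4-fold planted knockdown.

    120 accessible regions (60 factor-A-dependent, 60 factor-B-dependent) on
    4 x 100 kb chromosomes; knockdown of A scales A-dependent accessibility
    by 0.25. Candidates are the broadened true open regions; sensitivity is
    scored over A-dependent regions and the false-call rate over B-dependent
    (unchanged) ones.
    """
    cfg = SimConfig(
        seed=seed, n_chroms=4, chrom_length=100_000,
        n_sites_A=60, n_sites_B=60, n_sites_shared=0, n_unbound_sites=0,
        atac_depth=100_000, nfr_fraction=0.4, nuc_fraction=0.3,
        knockdown_scale=0.25,
    )
    genome, truth = simulate_genome(cfg)
    wt = simulate_atac(genome, truth, cfg, "wt")
    kd = simulate_atac(genome, truth, cfg, "knockdown_A")
    params = peaks.DifferentialParams()
    candidates = peaks.broaden(truth.open_regions, params.flank, genome)
    diff = peaks.differential_peaks(kd, wt, candidates, params)
    sens, false_rate = pipeline.differential_metrics(diff, truth)
    return {
        "sensitivity": sens, "false_call_rate": false_rate,
        "n_changed": sum(c in ("A", "shared") for c in truth.region_class),
        "n_unchanged": sum(c == "B" for c in truth.region_class),
        "n_called_closed": len(diff.closed_in_target()),
    }


def signal_ratio_study(seed: int = 1) -> dict[str, Any]:
    """Accessibility contrast between co-bound and single-factor regions.

    The generator assigns regions bound by both factors twice the
    accessibility weight of single-factor regions; the study summarizes mean
    signal in 1 kb windows per region class and reports the co-bound /
    single-factor ratio.
    """
    cfg = SimConfig(seed=seed)
    genome, truth = simulate_genome(cfg)
    track = simulate_track(genome, truth, cfg)
    label_map = {"A": "A_only", "B": "B_only", "shared": "AB_overlap"}
    table = RegionClassTable(
        list(truth.open_regions), [label_map[c] for c in truth.region_class]
    )
    from .annotate_signal import regionclass_signal_summary

    summary = regionclass_signal_summary(track, table, bin=1000)
    means = dict(zip(summary["label"], summary["mean"]))
    single = 0.5 * (means["A_only"] + means["B_only"])
    return {
        "ratio": means["AB_overlap"] / single,
        "mean_overlap": means["AB_overlap"],
        "mean_single": single,
        "n_regions": len(table),
    }


def determinism_study(seed: int, workdir: str | Path) -> dict[str, Any]:
    """Byte-identity of two end-to-end demo runs with the same config."""
    workdir = Path(workdir)
    m1, _ = pipeline.run_pipeline(pipeline.demo_config(workdir / "run1", seed))
    m2, _ = pipeline.run_pipeline(pipeline.demo_config(workdir / "run2", seed))
    return {
        "identical": float(m1["files"] == m2["files"]),
        "n_files": len(m1["files"]),
    }
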