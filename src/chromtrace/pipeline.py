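"""End-to-end orchestration of the simulated analysis, plus truth-channel verification.

``run_pipeline`` executes the stages in dependency order on a simulated
experiment — coverage, ChIP peaks for two factors, region classification,
background-zone normalization, motif scan + bound/unbound partition, dyad
calling and motif-dyad distances in two conditions, differential accessibility
under knockdown, TSS annotation and signal matrices — writing every output as
a plain text format and recording a manifest of content hashes.
``verify_against_truth`` scores the run against the generator's ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import annotate_signal, atac_norm, motif_nucleosome, peaks, region_classes
from .genome_io import (
    FragmentSet,
    GenomeModel,
    Interval,
    coverage_from_fragments,
    write_bedgraph,
    write_intervals,
)
from .synthetic_data import (
    GroundTruth,
    SimConfig,
    simulate_atac,
    simulate_chip,
    simulate_genome,
    simulate_track,
)

logger = logging.getLogger("chromtrace")

# Verification thresholds (high-SNR demo conditions)
THRESHOLDS = {
    "peak_sensitivity": 0.95,
    "peak_precision": 0.90,
    "dyad_recovery": 0.90,
    "norm_abs_z_mean": 0.05,
    "norm_abs_z_sd_err": 0.05,
    "classification_accuracy": 0.95,
    "differential_sensitivity": 1.0,
    "differential_false_rate": 0.05,
    "shift_ks_alpha": 0.01,
}


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails schema validation."""


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    chip_peaks: peaks.PeakCallParams = field(default_factory=peaks.PeakCallParams.chip)
    # ATAC peaks only generate broad candidate regions here; a loose fold gate
    # keeps candidate generation sensitive (differential calling applies its
    # own fold and significance gates)
    atac_peaks: peaks.PeakCallParams = field(
        default_factory=lambda: peaks.PeakCallParams.atac(min_fold=2.0)
    )
    differential: peaks.DifferentialParams = field(default_factory=peaks.DifferentialParams)
    normalization: atac_norm.NormalizationParams = field(
        default_factory=atac_norm.NormalizationParams
    )
    dyads: motif_nucleosome.DyadCallParams = field(
        default_factory=motif_nucleosome.DyadCallParams
    )
    matrix: annotate_signal.MatrixParams = field(default_factory=annotate_signal.MatrixParams)
    motif_max_mismatch: int = 1
    promoter_flank: int = 3000
    outdir: str = "results/pipeline"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # the single top-level seed flows into every stochastic stage
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        self.normalization = dataclasses.replace(self.normalization, seed=self.seed)

    _BLOCKS = {
        "sim": SimConfig,
        "chip_peaks": peaks.PeakCallParams,
        "atac_peaks": peaks.PeakCallParams,
        "differential": peaks.DifferentialParams,
        "normalization": atac_norm.NormalizationParams,
        "dyads": motif_nucleosome.DyadCallParams,
        "matrix": annotate_signal.MatrixParams,
    }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        scalar_fields = {
            f.name for f in dataclasses.fields(cls) if f.name not in cls._BLOCKS
        }
        for key, value in d.items():
            if key in cls._BLOCKS:
                block_cls = cls._BLOCKS[key]
                valid = {f.name for f in dataclasses.fields(block_cls)}
                unknown = set(value) - valid
                if unknown:
                    raise ConfigError(f"unknown keys {sorted(unknown)} in block {key!r}")
                coerced = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                }
                try:
                    kwargs[key] = block_cls(**coerced)
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"invalid block {key!r}: {exc}") from None
            elif key in scalar_fields:
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown configuration key {key!r}")
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def demo_config(outdir: str | Path = "results/pipeline", seed: int = 0) -> PipelineConfig:
    """Built-in demo: a 2 x 100 kb genome, modest depths, zone extension sized
    so signal zones do not swallow the toy genome."""
    return PipelineConfig(
        sim=SimConfig(seed=seed, atac_depth=40_000),
        normalization=atac_norm.NormalizationParams(
            signal_zone_extension=2000, n_random_regions=20_000, seed=seed
        ),
        outdir=str(outdir),
        seed=seed,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> tuple[dict[str, Any], dict[str, Any]]:
    """Run every stage; returns (manifest, in-memory artifacts).

    The manifest lists each output file with its SHA-256 content hash; a rerun
    with the same config reproduces identical hashes. A stage failure aborts
    with the stage name and the partial manifest attached to the exception.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    logger.info("pipeline config: %s", json.dumps(config.to_dict(), sort_keys=True))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"stages": [], "files": {}}
    art: dict[str, Any] = {}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            manifest["files"][str(p.relative_to(outdir))] = _sha256(p)

    stage = "simulate"
    try:
        genome, truth = simulate_genome(config.sim)
        art["genome"], art["truth"] = genome, truth
        genome.to_fasta(outdir / "genome.fa")
        genome.to_chrom_sizes(outdir / "genome.chrom.sizes")
        truth.write(outdir / "truth")
        config.sim.to_json(outdir / "sim_config.json")
        record(
            stage,
            outdir / "genome.fa",
            outdir / "genome.chrom.sizes",
            outdir / "sim_config.json",
            *sorted((outdir / "truth").iterdir()),
        )

        stage = "chip_peaks"
        chip_input = simulate_chip(genome, truth, config.sim, "input")
        peak_sets: dict[str, peaks.PeakSet] = {}
        for factor in ("A", "B"):
            frags = simulate_chip(genome, truth, config.sim, factor)
            ps = peaks.call_peaks(
                frags, chip_input, genome, config.chip_peaks, sample_label=f"chip_{factor}"
            )
            ps = peaks.remove_blacklisted(ps, [])
            ps.to_bed(outdir / f"peaks_{factor}.bed")
            peak_sets[factor] = ps
            art[f"chip_{factor}"] = frags
        art["peaks"] = peak_sets
        record(stage, outdir / "peaks_A.bed", outdir / "peaks_B.bed")

        stage = "classify"
        table = region_classes.classify_regions(peak_sets["A"], peak_sets["B"])
        venn = region_classes.overlap_venn(peak_sets["A"], peak_sets["B"])
        table.to_bed(outdir / "region_classes.bed")
        art["classes"], art["venn"] = table, venn
        record(stage, outdir / "region_classes.bed")

        stage = "atac_coverage"
        atac: dict[str, FragmentSet] = {
            cond: simulate_atac(genome, truth, config.sim, cond)
            for cond in ("wt", "knockdown_A", "overexpress_A")
        }
        art["atac"] = atac
        cov_wt = coverage_from_fragments(atac["wt"], genome)
        art["cov_wt"] = cov_wt
        write_bedgraph(cov_wt, outdir / "atac_wt.rpm.bedgraph")
        record(stage, outdir / "atac_wt.rpm.bedgraph")

        stage = "normalize"
        zones = atac_norm.define_background_zones(cov_wt, genome, config.normalization)
        model = atac_norm.sample_background(cov_wt, zones, config.normalization, genome)
        norm = atac_norm.normalize_track(cov_wt, model, config.normalization)
        model.to_json(outdir / "background_model.json")
        write_bedgraph(
            norm.as_track(genome.chrom_lengths), outdir / "atac_wt.norm.bedgraph"
        )
        art["background_zones"], art["background_model"], art["normalized"] = zones, model, norm
        record(stage, outdir / "background_model.json", outdir / "atac_wt.norm.bedgraph")

        stage = "motif_scan"
        motif = motif_nucleosome.MotifModel(
            consensus=truth.motif, max_mismatch=config.motif_max_mismatch
        )
        matches = motif_nucleosome.scan_motif(genome, motif)
        matches = motif_nucleosome.partition_bound(matches, peak_sets["A"])
        write_intervals(matches.intervals(), outdir / "motif_matches.bed")
        art["matches"] = matches
        record(stage, outdir / "motif_matches.bed")

        stage = "dyads_distances"
        atac_peaks_wt = peaks.call_peaks(atac["wt"], None, genome, config.atac_peaks)
        broad = peaks.broaden(atac_peaks_wt, config.differential.flank, genome)
        art["broad_peaks"] = broad
        dists: dict[str, dict[str, motif_nucleosome.DistanceDistribution]] = {}
        for cond in ("wt", "overexpress_A"):
            dyads = motif_nucleosome.call_dyads(
                atac[cond], broad, config.dyads, genome.chrom_lengths
            )
            art[f"dyads_{cond}"] = dyads
            dd = motif_nucleosome.motif_dyad_distances(matches, dyads, condition=cond)
            dists[cond] = dd
            for cat, dist in dd.items():
                dist.to_tsv(outdir / f"distances_{cond}_{cat}.tsv")
        art["distances"] = dists
        shift: dict[str, tuple[float, float, float]] = {}
        for cat in ("bound", "unbound"):
            if cat in dists["wt"] and cat in dists["overexpress_A"]:
                shift[cat] = motif_nucleosome.distribution_shift_test(
                    dists["wt"][cat], dists["overexpress_A"][cat]
                )
        art["shift"] = shift
        (outdir / "shift_tests.json").write_text(
            json.dumps(
                {
                    cat: {"ks": s[0], "p": s[1], "median_shift": s[2]}
                    for cat, s in shift.items()
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        record(
            stage,
            *sorted(outdir.glob("distances_*.tsv")),
            outdir / "shift_tests.json",
        )

        stage = "differential"
        diff = peaks.differential_peaks(
            atac["knockdown_A"], atac["wt"], broad, config.differential
        )
        diff.to_bed(outdir / "differential_peaks.bed")
        art["differential"] = diff
        record(stage, outdir / "differential_peaks.bed")

        stage = "annotate"
        tss = annotate_signal.TSSTable(truth.tss_table)
        ann = annotate_signal.annotate_nearest_tss(
            table.regions, tss, config.promoter_flank
        )
        ann.to_csv(outdir / "region_annotation.tsv", sep="\t", index=False)
        art["tss"], art["annotation"] = tss, ann
        record(stage, outdir / "region_annotation.tsv")

        stage = "matrices"
        if len(table) > 0:
            mat = annotate_signal.signal_matrix(cov_wt, table.regions, config.matrix)
            mat.to_tsv(outdir / "signal_matrix.tsv", labels=["atac_wt"])
            summary = annotate_signal.regionclass_signal_summary(cov_wt, table)
            summary.to_csv(outdir / "class_signal_summary.tsv", sep="\t", index=False)
            art["matrix"], art["class_summary"] = mat, summary
            record(stage, outdir / "signal_matrix.tsv",
                   outdir / "class_signal_summary.tsv")
        else:
            warnings.warn("no classified regions; matrices stage skipped")
            manifest["stages"].append("matrices(skipped)")
    except Exception as exc:
        exc.stage = stage          # type: ignore[attr-defined]
        exc.partial_manifest = manifest  # type: ignore[attr-defined]
        raise

    manifest["config"] = config.to_dict()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest, art


# ---------------------------------------------------------------------------
# truth-channel metrics


def center_recovery(
    predicted: list[Interval], truth_sites: list[Interval], tol: int
) -> tuple[float, float]:
    """(sensitivity, precision) matching predicted centers to true site centers
    within ``tol`` bp."""
    truth_by_chrom: dict[str, np.ndarray] = {}
    for s in truth_sites:
        truth_by_chrom.setdefault(s.chrom, []).append(s.center)  # type: ignore[arg-type]
    truth_by_chrom = {c: np.sort(np.asarray(v)) for c, v in truth_by_chrom.items()}

    def near(chrom: str, pos: int, index: dict[str, np.ndarray]) -> bool:
        arr = index.get(chrom)
        if arr is None or arr.size == 0:
            return False
        i = int(np.searchsorted(arr, pos))
        return any(
            abs(pos - int(arr[j])) <= tol for j in (i - 1, i) if 0 <= j < arr.size
        )

    pred_by_chrom: dict[str, np.ndarray] = {}
    for p in predicted:
        pred_by_chrom.setdefault(p.chrom, []).append(p.center)  # type: ignore[arg-type]
    pred_by_chrom = {c: np.sort(np.asarray(v)) for c, v in pred_by_chrom.items()}
    if not truth_sites:
        return float("nan"), float("nan")
    sens = np.mean([near(s.chrom, s.center, pred_by_chrom) for s in truth_sites])
    prec = (
        np.mean([near(p.chrom, p.center, truth_by_chrom) for p in predicted])
        if predicted
        else float("nan")
    )
    return float(sens), float(prec)


def dyad_recovery(
    called: motif_nucleosome.DyadSet,
    truth_dyads: dict[str, np.ndarray],
    tol: int = 20,
    restrict_to_regions: bool = True,
) -> float:
    """Fraction of true dyads with a called dyad within ``tol`` bp."""
    region_index = None
    if restrict_to_regions and called.regions:
        from .genome_io import intervals_by_chrom, overlaps_any

        region_index = intervals_by_chrom(called.regions)
    total = hit = 0
    for chrom, arr in truth_dyads.items():
        pos = called.positions(chrom)
        for t in arr:
            if region_index is not None and not overlaps_any(
                Interval(chrom, int(t), int(t) + 1), region_index
            ):
                continue
            total += 1
            if pos.size:
                i = int(np.searchsorted(pos, t))
                if any(
                    abs(int(t) - int(pos[j])) <= tol
                    for j in (i - 1, i)
                    if 0 <= j < pos.size
                ):
                    hit += 1
    return hit / total if total else float("nan")


def classification_accuracy(
    table: region_classes.RegionClassTable, truth: GroundTruth
) -> float:
    """Fraction of merged regions whose label matches the planted site classes
    they contain (regions containing no planted site are ignored)."""
    from .genome_io import intervals_by_chrom, overlaps_any

    idx_A = intervals_by_chrom(truth.bound_sites_A + truth.bound_sites_shared)
    idx_B = intervals_by_chrom(truth.bound_sites_B + truth.bound_sites_shared)
    total = ok = 0
    for region, label in zip(table.regions, table.labels):
        has_a = overlaps_any(region, idx_A)
        has_b = overlaps_any(region, idx_B)
        if not (has_a or has_b):
            continue
        expected = "AB_overlap" if (has_a and has_b) else ("A_only" if has_a else "B_only")
        total += 1
        ok += label == expected
    return ok / total if total else float("nan")


def differential_metrics(
    diff: peaks.DifferentialPeakSet, truth: GroundTruth
) -> tuple[float, float]:
    """(sensitivity over A-dependent regions, false-call rate over unchanged ones)."""
    from .genome_io import intervals_by_chrom, overlaps_any

    closed = [
        Interval(p.chrom, p.start, p.end) for p in diff.closed_in_target()
    ]
    idx = intervals_by_chrom(closed) if closed else {}
    changed = [
        r
        for r, c in zip(truth.open_regions, truth.region_class)
        if c in ("A", "shared")
    ]
    unchanged = [
        r for r, c in zip(truth.open_regions, truth.region_class) if c == "B"
    ]
    sens = (
        np.mean([overlaps_any(r, idx) for r in changed]) if changed else float("nan")
    )
    false = (
        np.mean([overlaps_any(r, idx) for r in unchanged])
        if unchanged
        else float("nan")
    )
    return float(sens), float(false)


def background_z_stats(
    norm: atac_norm.NormalizedTrack,
    background_zones: list[Interval],
    params: atac_norm.NormalizationParams,
    chrom_lengths: dict[str, int],
    seed_offset: int = 1,
) -> tuple[float, float]:
    """Mean and SD of z over positive bases of freshly sampled background regions."""
    from .genome_io import contained_in_any, intervals_by_chrom

    rng = np.random.default_rng(params.seed + seed_offset)
    index = intervals_by_chrom(background_zones)
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    rl = params.random_region_length
    which = rng.choice(len(chroms), size=params.n_random_regions, p=lens / lens.sum())
    u = rng.random(params.n_random_regions)
    chunks = []
    for i in range(params.n_random_regions):
        c = chroms[which[i]]
        hi = chrom_lengths[c] - rl
        if hi < 0:
            continue
        s = int(u[i] * (hi + 1))
        if contained_in_any(c, s, s + rl, index):
            chunks.append(norm.z[c][s : s + rl])
    vals = np.concatenate(chunks)
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def verify_against_truth(
    artifacts: dict[str, Any],
    truth: GroundTruth | None = None,
    config: PipelineConfig | None = None,
) -> dict[str, Any]:
    """Score a simulated run's artifacts against the generator's ground truth."""
    truth = truth or artifacts.get("truth")
    if truth is None:
        raise ValueError("no truth channel: verification requires a simulated run")
    config = config or PipelineConfig()
    report: dict[str, Any] = {}

    ps = artifacts["peaks"]["A"]
    tol = (ps.params.window if ps.params else 200) // 2
    sens, prec = center_recovery(ps.intervals(), truth.bound_sites("A"), tol)
    report["peak_sensitivity"] = sens
    report["peak_precision"] = prec

    report["classification_accuracy"] = classification_accuracy(
        artifacts["classes"], truth
    )

    genome: GenomeModel = artifacts["genome"]
    z_mean, z_sd = background_z_stats(
        artifacts["normalized"],
        artifacts["background_zones"],
        config.normalization,
        genome.chrom_lengths,
    )
    report["norm_background_z_mean"] = z_mean
    report["norm_background_z_sd"] = z_sd

    report["dyad_recovery"] = dyad_recovery(
        artifacts["dyads_wt"], truth.true_dyads["wt"]
    )

    shift = artifacts.get("shift", {})
    if "bound" in shift:
        report["bound_median_shift"] = shift["bound"][2]
        report["bound_shift_p"] = shift["bound"][1]
    if "unbound" in shift:
        report["unbound_median_shift"] = shift["unbound"][2]

    d_sens, d_false = differential_metrics(artifacts["differential"], truth)
    report["differential_sensitivity"] = d_sens
    report["differential_false_rate"] = d_false

    t = THRESHOLDS
    report["checks"] = {
        "peaks": sens >= t["peak_sensitivity"] and prec >= t["peak_precision"],
        "classification": report["classification_accuracy"] >= t["classification_accuracy"],
        "normalization": abs(z_mean) < t["norm_abs_z_mean"]
        and abs(z_sd - 1.0) < t["norm_abs_z_sd_err"],
        "dyads": report["dyad_recovery"] >= t["dyad_recovery"],
        "differential": d_sens >= t["differential_sensitivity"]
        and d_false < t["differential_false_rate"],
        "shift": shift.get("bound", (0, 1, 0))[1] < t["shift_ks_alpha"]
        if "bound" in shift
        else False,
    }
    return report
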