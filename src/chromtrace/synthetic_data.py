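"""Synthetic genomes, ChIP/ATAC fragment sets and ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: uniform/log-normal background fragment noise, ChIP enrichment
centered on planted bound motifs, sub-nucleosomal vs nucleosomal (120-200 bp)
ATAC fragment classes, nucleosome dyad-protected footprints, genotype-dependent
accessibility loss, and condition-dependent nucleosome displacement at bound
motifs. Every stage of the pipeline is testable against the returned truth
channel with no external download.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import (
    CoverageTrack,
    FragmentSet,
    GenomeModel,
    Interval,
    merge_intervals,
    write_intervals,
)

# Conditions: wild type, RNAi knockdown / genetic knockout of factor A,
# ectopic overexpression of A, and knockdown of factor B.
CONDITIONS = ("wt", "knockdown_A", "ko_A", "overexpress_A", "knockdown_B")

#: Zic-family-like 12 bp consensus used as the default planted binding motif.
DEFAULT_MOTIF = "caacgcccgcca"

#: SD (bp) of nucleosomal-fragment midpoints around the true dyad. Fixed so the
#: +/-20 bp dyad-recovery checks are meaningful without being trivial.
DYAD_JITTER_SD = 20.0

# integer stream tags so each sample draws from an independent, seeded stream
_STREAM = {
    "genome": 0,
    "chip_A": 1,
    "chip_B": 2,
    "chip_input": 3,
    "track": 4,
    "wt": 10,
    "knockdown_A": 11,
    "ko_A": 12,
    "overexpress_A": 13,
    "knockdown_B": 14,
}


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    Counts are totals over the whole simulated genome unless stated otherwise.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 100_000
    n_tss: int = 40
    n_sites_A: int = 12          # bound sites for factor A only
    n_sites_B: int = 12          # bound sites for factor B only
    n_sites_shared: int = 8      # sites bound by both factors
    n_unbound_sites: int = 30    # motif copies planted in closed background
    motif: str = DEFAULT_MOTIF
    open_region_width: int = 600
    chip_enrichment: float = 8.0     # fold coverage over background at site centers
    chip_fragment_sd: float = 60.0   # bp spread of enriched ChIP fragment centers
    chip_depth_per_100kb: int = 5000  # background ChIP fragments per 100 kb
    atac_depth: int = 50_000         # total ATAC fragments per sample (exact)
    nfr_fraction: float = 0.35       # share of sub-nucleosomal open-region fragments
    nuc_fraction: float = 0.35       # share of nucleosomal fragments
    nucleosomal_band: tuple[int, int] = (120, 200)
    dyad_spacing: int = 150          # bp from site center to first flanking dyad
    displacement_delta: int = 80     # outward dyad shift at bound A sites (overexpress)
    knockdown_scale: float = 0.25    # accessibility multiplier at A-dependent regions
    background_lognormal: tuple[float, float] = (1.0, 0.5)  # (mu, sigma) of log2 RPM
    signal_amplitude: float = 50.0   # RPM added at open regions in direct tracks

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_tss", "atac_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_sites_A", "n_sites_B", "n_sites_shared", "n_unbound_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.knockdown_scale <= 1.0:
            raise ValueError("knockdown_scale must be in [0, 1]")
        lo, hi = self.nucleosomal_band
        if not (100 <= lo < hi <= 250):
            raise ValueError("nucleosomal_band must satisfy 100 <= min < max <= 250")
        if self.nfr_fraction + self.nuc_fraction > 1.0:
            raise ValueError("nfr_fraction + nuc_fraction must be <= 1")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stream]])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


@dataclass
class GroundTruth:
    """Truth channel for parameter-recovery tests."""

    bound_sites_A: list[Interval]
    bound_sites_B: list[Interval]
    bound_sites_shared: list[Interval]
    unbound_sites: list[Interval]
    open_regions: list[Interval]
    region_class: list[str]                       # per open region: A / B / shared
    region_weights: dict[str, np.ndarray]         # per condition accessibility weight
    true_dyads: dict[str, dict[str, np.ndarray]]  # condition -> chrom -> dyad positions
    tss_table: list[tuple[str, str, int, str]]    # (gene, chrom, pos, strand)
    motif: str

    def bound_sites(self, factor: str) -> list[Interval]:
        if factor == "A":
            return self.bound_sites_A + self.bound_sites_shared
        if factor == "B":
            return self.bound_sites_B + self.bound_sites_shared
        raise ValueError(f"unknown factor {factor!r}")

    def all_sites(self) -> list[Interval]:
        return (
            self.bound_sites_A
            + self.bound_sites_B
            + self.bound_sites_shared
            + self.unbound_sites
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_intervals(self.bound_sites_A, outdir / "sites_A.bed")
        write_intervals(self.bound_sites_B, outdir / "sites_B.bed")
        write_intervals(self.bound_sites_shared, outdir / "sites_shared.bed")
        write_intervals(self.unbound_sites, outdir / "sites_unbound.bed")
        write_intervals(self.open_regions, outdir / "open_regions.bed")
        with open(outdir / "tss.tsv", "w") as fh:
            for gene, chrom, pos, strand in self.tss_table:
                fh.write(f"{gene}\t{chrom}\t{pos}\t{strand}\n")


_COMPLEMENT = str.maketrans("acgtACGT", "tgcaTGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_genome(cfg: SimConfig) -> tuple[GenomeModel, GroundTruth]:
    """Random genome with planted motif sites, open regions, dyads and TSSs.

    Bound sites (classes A, B, shared) sit at the centers of open (accessible)
    regions; unbound motif copies are planted in closed background. The motif is
    placed on the + strand at even-indexed sites and as its reverse complement
    (- strand) otherwise, so scanning must be strand-aware. Deterministic given
    ``cfg.seed``.
    """
    rng = cfg.rng("genome")
    motif = cfg.motif.upper()
    mlen = len(motif)

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    lengths = {c: cfg.chrom_length for c in chroms}
    seqs = {
        c: "".join(rng.choice(list("ACGT"), size=cfg.chrom_length))
        for c in chroms
    }

    # Candidate slots on a fixed pitch, margin away from chromosome ends, so
    # open regions and their flanking dyad arrays never collide or run off.
    pitch = 2000
    margin = 1200
    slots: list[tuple[str, int]] = []
    for c in chroms:
        for pos in range(margin, cfg.chrom_length - margin, pitch):
            slots.append((c, pos))
    n_bound = cfg.n_sites_A + cfg.n_sites_B + cfg.n_sites_shared
    n_needed = n_bound + cfg.n_unbound_sites
    if n_needed > len(slots):
        raise ValueError(
            f"{n_needed} sites requested but only {len(slots)} placeable slots"
        )
    order = rng.permutation(len(slots))
    chosen = [slots[i] for i in order[:n_needed]]

    seq_arrays = {c: np.frombuffer(seqs[c].encode(), dtype="S1").copy() for c in chroms}

    def plant(idx: int, chrom: str, center: int) -> Interval:
        start = center - mlen // 2
        strand = "+" if idx % 2 == 0 else "-"
        inserted = motif if strand == "+" else reverse_complement(motif)
        seq_arrays[chrom][start : start + mlen] = np.frombuffer(
            inserted.encode(), dtype="S1"
        )
        return Interval(chrom, start, start + mlen, name=f"site{idx:04d}", strand=strand)

    sites_A: list[Interval] = []
    sites_B: list[Interval] = []
    sites_shared: list[Interval] = []
    unbound: list[Interval] = []
    open_regions: list[Interval] = []
    region_class: list[str] = []
    half_w = cfg.open_region_width // 2
    for idx, (chrom, center) in enumerate(chosen):
        site = plant(idx, chrom, center)
        if idx < cfg.n_sites_A:
            sites_A.append(site)
            cls = "A"
        elif idx < cfg.n_sites_A + cfg.n_sites_B:
            sites_B.append(site)
            cls = "B"
        elif idx < n_bound:
            sites_shared.append(site)
            cls = "shared"
        else:
            unbound.append(site)
            continue
        open_regions.append(Interval(chrom, center - half_w, center + half_w))
        region_class.append(cls)

    genome = GenomeModel(lengths, {c: seq_arrays[c].tobytes().decode() for c in chroms})

    # Per-condition accessibility weights: shared (A+B) regions are twice as
    # accessible as single-factor regions in wild type; A-dependent regions
    # (A and shared) collapse by knockdown_scale when A is depleted, B-dependent
    # regions likewise for B.
    base = np.array([2.0 if c == "shared" else 1.0 for c in region_class])
    is_A_dep = np.array([c in ("A", "shared") for c in region_class])
    is_B_dep = np.array([c in ("B", "shared") for c in region_class])
    weights = {
        "wt": base.copy(),
        "overexpress_A": base.copy(),
        "knockdown_A": np.where(is_A_dep, base * cfg.knockdown_scale, base),
        "ko_A": np.where(is_A_dep, base * cfg.knockdown_scale, base),
        "knockdown_B": np.where(is_B_dep, base * cfg.knockdown_scale, base),
    }

    # Nucleosome dyads flank every planted site: two on each side, the first at
    # dyad_spacing from the site center. Under overexpression of A, the arrays
    # flanking bound A/shared sites shift outward by displacement_delta.
    d1, d2 = cfg.dyad_spacing, cfg.dyad_spacing + 180
    a_bound_centers = {(s.chrom, s.center) for s in sites_A + sites_shared}
    dyads: dict[str, dict[str, list[int]]] = {
        cond: {c: [] for c in chroms} for cond in CONDITIONS
    }
    for site in sites_A + sites_B + sites_shared + unbound:
        c, center = site.chrom, site.center
        for cond in CONDITIONS:
            delta = (
                cfg.displacement_delta
                if cond == "overexpress_A" and (c, center) in a_bound_centers
                else 0
            )
            for off in (d1, d2):
                dyads[cond][c].extend((center - off - delta, center + off + delta))
    true_dyads = {
        cond: {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in per.items()}
        for cond, per in dyads.items()
    }

    # TSSs: one near each open region (gene association for annotation tests),
    # the remainder uniform background genes.
    tss: list[tuple[str, str, int, str]] = []
    n_linked = min(cfg.n_tss, len(open_regions))
    for i in range(n_linked):
        reg = open_regions[i]
        pos = int(np.clip(reg.center + rng.normal(0, 300), 0, cfg.chrom_length - 1))
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append((f"gene{i:04d}", reg.chrom, pos, strand))
    for i in range(n_linked, cfg.n_tss):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(0, cfg.chrom_length))
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append((f"gene{i:04d}", chrom, pos, strand))

    truth = GroundTruth(
        bound_sites_A=sites_A,
        bound_sites_B=sites_B,
        bound_sites_shared=sites_shared,
        unbound_sites=unbound,
        open_regions=open_regions,
        region_class=region_class,
        region_weights=weights,
        true_dyads=true_dyads,
        tss_table=tss,
        motif=motif,
    )
    return genome, truth


def _uniform_fragments(
    rng: np.random.Generator,
    genome: GenomeModel,
    n: int,
    len_lo: int,
    len_hi: int,
) -> list[Interval]:
    chroms = genome.chrom_names
    lens_bp = np.array([genome.length(c) for c in chroms], dtype=float)
    which = rng.choice(len(chroms), size=n, p=lens_bp / lens_bp.sum())
    frag_len = rng.integers(len_lo, len_hi + 1, size=n)
    out = []
    for i in range(n):
        c = chroms[which[i]]
        L = genome.length(c)
        fl = int(min(frag_len[i], L))
        start = int(rng.integers(0, L - fl + 1))
        out.append(Interval(c, start, start + fl))
    return out


def simulate_chip(
    genome: GenomeModel, truth: GroundTruth, cfg: SimConfig, factor: str
) -> FragmentSet:
    """ChIP fragments for one factor: uniform background plus site-centered pileups.

    Enriched fragment centers are Normal(site center, chip_fragment_sd); per-site
    enriched counts are Poisson with mean (enrichment - 1) x expected background
    coverage, so coverage at site centers is ~enrichment-fold over background and
    enrichment = 1 is an exact null. ``factor='input'`` gives background only.
    """
    if factor not in ("A", "B", "input"):
        raise ValueError(f"unknown factor {factor!r}")
    rng = cfg.rng(f"chip_{factor}" if factor != "input" else "chip_input")
    L = genome.total_length
    n_bg = max(1, round(cfg.chip_depth_per_100kb * L / 100_000))
    frags = _uniform_fragments(rng, genome, n_bg, 150, 300)
    if factor != "input":
        mean_len = 225.5
        bg_cov = n_bg * mean_len / L  # expected background fragments over a base
        extra = max(0.0, (cfg.chip_enrichment - 1.0) * bg_cov)
        for site in truth.bound_sites(factor):
            n_e = int(rng.poisson(extra))
            if n_e == 0:
                continue
            centers = rng.normal(site.center, cfg.chip_fragment_sd, size=n_e)
            lens = rng.integers(150, 301, size=n_e)
            Lc = genome.length(site.chrom)
            for c, fl in zip(centers, lens):
                start = int(np.clip(round(c - fl / 2), 0, Lc - fl))
                frags.append(Interval(site.chrom, start, start + int(fl)))
    return FragmentSet(frags, paired=True)


def simulate_atac(
    genome: GenomeModel, truth: GroundTruth, cfg: SimConfig, condition: str
) -> FragmentSet:
    """ATAC fragments for one condition; exactly ``cfg.atac_depth`` fragments.

    Three classes: sub-nucleosomal (< 100 bp) fragments concentrated in open
    regions in proportion to condition-specific accessibility weights;
    nucleosomal fragments with midpoints Normal(true dyad, 20 bp) and lengths
    uniform in the nucleosomal band; background fragments placed by a per-1 kb
    log-normal rate (so the normalization module's background assumption is
    realizable). Accessibility lost under knockdown is reassigned to background,
    keeping total depth fixed while planted regions drop by the intended fold.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = cfg.rng(condition)
    n_sub_budget = round(cfg.atac_depth * cfg.nfr_fraction)
    n_nuc = round(cfg.atac_depth * cfg.nuc_fraction)
    n_bg = cfg.atac_depth - n_sub_budget - n_nuc
    frags: list[Interval] = []

    # --- sub-nucleosomal, open-region fragments ---
    if truth.open_regions and n_sub_budget > 0:
        w_cond = truth.region_weights[condition].astype(float)
        w_wt = truth.region_weights["wt"].astype(float)
        widths = np.array([r.width for r in truth.open_regions], dtype=float)
        rates = w_cond * widths
        rates_wt = w_wt * widths
        # normalize against the wild-type total: depleted mass goes to background
        p = rates / rates_wt.sum()
        p = np.append(np.minimum(p, 1.0), max(0.0, 1.0 - p.sum()))
        p /= p.sum()
        counts = rng.multinomial(n_sub_budget, p)
        n_bg += int(counts[-1])
        for reg, k in zip(truth.open_regions, counts[:-1]):
            if k == 0:
                continue
            lens = rng.integers(40, 100, size=k)
            starts = reg.start + rng.integers(0, np.maximum(reg.width - lens, 1))
            Lc = genome.length(reg.chrom)
            for s, fl in zip(starts, lens):
                s = int(np.clip(s, 0, Lc - fl))
                frags.append(Interval(reg.chrom, s, s + int(fl)))
    else:
        n_bg += n_sub_budget

    # --- nucleosomal fragments around condition-specific dyads ---
    dyads = truth.true_dyads[condition]
    flat = [(c, int(p)) for c, arr in dyads.items() for p in arr]
    if flat and n_nuc > 0:
        lo, hi = cfg.nucleosomal_band
        counts = rng.multinomial(n_nuc, np.full(len(flat), 1.0 / len(flat)))
        for (chrom, pos), k in zip(flat, counts):
            if k == 0:
                continue
            mids = rng.normal(pos, DYAD_JITTER_SD, size=k)
            lens = rng.integers(lo, hi + 1, size=k)
            Lc = genome.length(chrom)
            for m, fl in zip(mids, lens):
                start = int(np.clip(round(m - fl / 2), 0, Lc - fl))
                frags.append(Interval(chrom, start, start + int(fl)))
    else:
        n_bg += n_nuc

    # --- background fragments, log-normal per-block rate ---
    # Background models closed chromatin: it is placed in the genome
    # complement of the open regions, so open-region signal is carried by the
    # accessibility classes alone and planted fold changes are realized as
    # stated.
    if n_bg > 0:
        mu, sigma = cfg.background_lognormal
        block = 1000
        open_by_chrom: dict[str, list[Interval]] = {c: [] for c in genome.chrom_names}
        for reg in merge_intervals(truth.open_regions):
            open_by_chrom[reg.chrom].append(reg)
        block_index: list[tuple[str, int, int]] = []
        for c in genome.chrom_names:
            Lc = genome.length(c)
            pos = 0
            segments = []
            for reg in open_by_chrom[c]:
                if reg.start > pos:
                    segments.append((pos, reg.start))
                pos = max(pos, reg.end)
            if pos < Lc:
                segments.append((pos, Lc))
            for seg_s, seg_e in segments:
                for s in range(seg_s, seg_e, block):
                    block_index.append((c, s, min(s + block, seg_e)))
        rate = np.exp2(rng.normal(mu, sigma, size=len(block_index)))
        rate *= np.array([e - s for _, s, e in block_index], dtype=float)
        counts = rng.multinomial(n_bg, rate / rate.sum())
        for (chrom, s, e), k in zip(block_index, counts):
            if k == 0:
                continue
            lens = rng.integers(50, 151, size=k)
            Lc = genome.length(chrom)
            for fl in lens:
                start = int(rng.integers(s, e))
                start = int(np.clip(start, 0, Lc - fl))
                frags.append(Interval(chrom, start, start + int(fl)))

    assert len(frags) == cfg.atac_depth
    return FragmentSet(frags, paired=True)


def simulate_track(
    genome: GenomeModel, truth: GroundTruth, cfg: SimConfig, condition: str = "wt"
) -> CoverageTrack:
    """Direct per-bp RPM track: log-normal background plus open-region signal.

    Background bases are i.i.d. with log2(value) ~ Normal(mu, sigma) from
    ``cfg.background_lognormal`` — log-normal by construction, so background-model
    fitting has an exact truth to recover. Open regions additionally receive
    ``signal_amplitude x accessibility weight``.
    """
    rng = cfg.rng("track")
    data: dict[str, np.ndarray] = {}
    mu, sigma = cfg.background_lognormal
    for c in genome.chrom_names:
        data[c] = np.exp2(rng.normal(mu, sigma, size=genome.length(c)))
    w = truth.region_weights[condition]
    for reg, weight in zip(truth.open_regions, w):
        data[reg.chrom][reg.start : reg.end] += cfg.signal_amplitude * float(weight)
    return CoverageTrack(data, genome.chrom_lengths, bin=1, tag="RPM")
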