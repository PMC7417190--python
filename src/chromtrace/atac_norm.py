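"""Background-zone log-normal normalization of per-bp RPM coverage.

Fixed-width signal windows are called on the track and extended from their
centers into "signal zones"; the genome complement forms "background zones".
Random fixed-length regions falling entirely inside background zones sample
the background noise, whose strictly positive per-bp RPM values y are modeled
log-normally: mu and sigma are the mean and SD of log2(y). The whole track is
then centered and scaled,

    z = (log2 y - mu) / sigma,        ynorm = max(0, 2**z - pseudocount),

with z undefined (NaN) and ynorm = 0 wherever y = 0. z is the analysis-facing
value and is strictly increasing in y; ynorm is the non-negative browser-track
companion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .genome_io import (
    CoverageTrack,
    GenomeModel,
    Interval,
    contained_in_any,
    intervals_by_chrom,
    merge_intervals,
)


@dataclass
class NormalizationParams:
    peak_window: int = 150
    signal_zone_extension: int = 20_000   # total signal-zone width, centered
    n_random_regions: int = 100_000
    random_region_length: int = 150
    pseudocount: float = 1.0
    seed: int = 0
    peak_min_fold: float = 4.0            # window mean over genome mean to count as signal
    min_kept_regions: int = 100

    def __post_init__(self) -> None:
        for name in ("peak_window", "signal_zone_extension", "n_random_regions",
                     "random_region_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class BackgroundModel:
    mu: float        # mean of log2 of positive background RPM
    sigma: float     # SD of same
    n_scores: int    # positive background nucleotides used
    n_regions_kept: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_scores <= 0:
            raise ValueError("n_scores must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BackgroundModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class NormalizedTrack:
    z: dict[str, np.ndarray]       # NaN where raw y == 0
    ynorm: dict[str, np.ndarray]   # clamped at 0
    model: BackgroundModel
    bin: int = 1

    def as_track(self, chrom_lengths: dict[str, int]) -> CoverageTrack:
        return CoverageTrack(self.ynorm, chrom_lengths, bin=self.bin, tag="normalized")


def define_background_zones(
    track: CoverageTrack, genome: GenomeModel, params: NormalizationParams
) -> list[Interval]:
    """Genome complement of the merged, extended signal zones.

    Signal windows are ``peak_window`` bp candidates (step = window/2) whose
    mean track value is at least ``peak_min_fold`` times the genome-wide mean;
    each is extended from its center to ``signal_zone_extension`` total width.
    If no window qualifies the whole genome is background (with a warning).
    """
    if track.tag != "RPM":
        raise ValueError("background zones are defined on an RPM track")
    if track.bin != 1:
        raise ValueError("per-bp (bin=1) track required")
    w = params.peak_window
    genome_mean = float(
        np.concatenate([track.data[c] for c in genome.chrom_names]).mean()
    )
    half_ext = params.signal_zone_extension // 2
    zones: list[Interval] = []
    for chrom in genome.chrom_names:
        arr = track.data[chrom]
        L = genome.length(chrom)
        if L < w:
            continue
        cs = np.cumsum(np.concatenate([[0.0], arr]))
        starts = np.arange(0, L - w + 1, w // 2)
        means = (cs[starts + w] - cs[starts]) / w
        hit = starts[means >= params.peak_min_fold * genome_mean]
        for s in hit:
            center = int(s) + w // 2
            zones.append(
                Interval(chrom, max(0, center - half_ext), min(L, center + half_ext))
            )
    if not zones:
        warnings.warn("no signal windows found; background = whole genome")
        return [Interval(c, 0, genome.length(c)) for c in genome.chrom_names]
    signal = merge_intervals(zones)
    background: list[Interval] = []
    by_chrom: dict[str, list[Interval]] = {c: [] for c in genome.chrom_names}
    for iv in signal:
        by_chrom[iv.chrom].append(iv)
    for chrom in genome.chrom_names:
        L = genome.length(chrom)
        pos = 0
        for iv in by_chrom[chrom]:
            if iv.start > pos:
                background.append(Interval(chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < L:
            background.append(Interval(chrom, pos, L))
    return background


def sample_background(
    track: CoverageTrack,
    background_zones: list[Interval],
    params: NormalizationParams,
    genome: GenomeModel | None = None,
) -> BackgroundModel:
    """Fit the log-normal background model from random background regions.

    ``n_random_regions`` candidate regions of ``random_region_length`` bp are
    drawn uniformly over the genome (seeded); a candidate is kept iff it falls
    entirely inside a background zone. mu/sigma are the mean/SD of log2 of the
    strictly positive per-bp values in kept regions.
    """
    if not background_zones:
        raise ValueError("background zones are empty")
    chrom_lengths = (
        genome.chrom_lengths if genome is not None else track.chrom_lengths
    )
    rng = np.random.default_rng(params.seed)
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    rl = params.random_region_length
    index = intervals_by_chrom(background_zones)
    which = rng.choice(len(chroms), size=params.n_random_regions, p=lens / lens.sum())
    # one uniform draw per candidate, scaled to its chromosome
    u = rng.random(params.n_random_regions)
    kept = 0
    chunks: list[np.ndarray] = []
    for i in range(params.n_random_regions):
        c = chroms[which[i]]
        hi = chrom_lengths[c] - rl
        if hi < 0:
            continue
        s = int(u[i] * (hi + 1))
        if not contained_in_any(c, s, s + rl, index):
            continue
        kept += 1
        chunks.append(track.data[c][s : s + rl])
    if kept < params.min_kept_regions:
        raise ValueError(
            f"only {kept} random regions fell inside background zones "
            f"(minimum {params.min_kept_regions}); background unidentifiable"
        )
    vals = np.concatenate(chunks)
    pos = vals[vals > 0]
    if pos.size < 2:
        raise ValueError("fewer than 2 positive background scores")
    logs = np.log2(pos)
    sigma = float(np.std(logs, ddof=1))
    if sigma <= 0:
        raise ValueError("degenerate background (zero variance); model undefined")
    return BackgroundModel(
        mu=float(np.mean(logs)),
        sigma=sigma,
        n_scores=int(pos.size),
        n_regions_kept=kept,
        seed=params.seed,
    )


def normalize_track(
    track: CoverageTrack, model: BackgroundModel, params: NormalizationParams
) -> NormalizedTrack:
    """Center and scale log2 coverage by the background model (see module docs)."""
    z: dict[str, np.ndarray] = {}
    ynorm: dict[str, np.ndarray] = {}
    with np.errstate(divide="ignore"):
        for chrom, arr in track.data.items():
            zc = np.full(arr.shape, np.nan)
            posmask = arr > 0
            zc[posmask] = (np.log2(arr[posmask]) - model.mu) / model.sigma
            z[chrom] = zc
            yn = np.zeros(arr.shape)
            yn[posmask] = np.maximum(0.0, np.exp2(zc[posmask]) - params.pseudocount)
            ynorm[chrom] = yn
    return NormalizedTrack(z=z, ynorm=ynorm, model=model, bin=track.bin)
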