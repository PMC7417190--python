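"""Enrichment peak calling, blacklist filtering, broad peaks and differential peaks.

One declared scoring procedure serves both the ChIP and ATAC use cases:
fragment-midpoint counts in fixed-width candidate windows (step = window/2),
a Poisson upper tail against the max of local background, genome-wide
background and (when provided) a depth-scaled control count,
Benjamini-Hochberg q-values over all candidates, and greedy selection of
surviving windows honoring a minimum center distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genome_io import (
    FragmentSet,
    GenomeModel,
    Interval,
    intervals_by_chrom,
    merge_intervals,
    overlaps_any,
    write_intervals,
)


@dataclass
class PeakCallParams:
    """Window scoring parameters (ATAC-style defaults; use .chip() for ChIP)."""

    window: int = 150
    local_size: int = 50_000
    min_dist: int = 50
    q_threshold: float = 1e-5
    min_fold: float = 4.0

    def __post_init__(self) -> None:
        if self.window >= self.local_size:
            raise ValueError("window must be smaller than local_size")
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError("q_threshold must be in (0, 1)")

    @classmethod
    def atac(cls, **kw) -> "PeakCallParams":
        return cls(**{"window": 150, **kw})

    @classmethod
    def chip(cls, **kw) -> "PeakCallParams":
        # q-value is the primary gate for ChIP; the fold gate is kept loose
        # because the local lambda absorbs enrichment from neighboring sites
        return cls(**{"window": 200, "q_threshold": 1e-5, "min_fold": 2.0, **kw})


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    count: int
    fold: float
    p: float
    q: float

    @property
    def center(self) -> int:
        return self.start + (self.end - self.start) // 2

    def to_interval(self) -> Interval:
        return Interval(
            self.chrom, self.start, self.end,
            score=-math.log10(max(self.q, 1e-300)),
        )


@dataclass
class PeakSet:
    """Called peaks plus the parameters and sample label that produced them."""

    peaks: list[Peak]
    sample_label: str = ""
    params: PeakCallParams | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def intervals(self) -> list[Interval]:
        return [p.to_interval() for p in self.peaks]

    def to_bed(self, path: str | Path) -> None:
        write_intervals(self.intervals(), path)


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _candidate_grid(length: int, window: int) -> np.ndarray:
    if length < window:
        return np.empty(0, dtype=np.int64)
    return np.arange(0, length - window + 1, window // 2, dtype=np.int64)


def score_windows(
    signal: FragmentSet,
    background: FragmentSet | None,
    genome: GenomeModel,
    params: PeakCallParams,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-chromosome candidate starts, midpoint counts, lambdas, p-values.

    The local background mean is taken over a ``local_size`` window centered on
    the candidate, excluding the candidate window itself.
    """
    if signal.total_count == 0:
        raise ValueError("cannot call peaks on an empty fragment set")
    if background is not None and background.total_count == 0:
        raise ValueError("background fragment set has zero depth")
    w = params.window
    mids = signal.midpoints()
    total = signal.total_count
    rate = total / genome.total_length
    bg_mids = background.midpoints() if background is not None else None
    depth_ratio = total / background.total_count if background is not None else 0.0
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom in genome.chrom_names:
        L = genome.length(chrom)
        starts = _candidate_grid(L, w)
        if starts.size == 0:
            continue
        m = mids.get(chrom, np.empty(0, dtype=np.int64))
        k = np.searchsorted(m, starts + w) - np.searchsorted(m, starts)
        centers = starts + w // 2
        lo = np.clip(centers - params.local_size // 2, 0, L)
        hi = np.clip(centers + params.local_size // 2, 0, L)
        local_k = np.searchsorted(m, hi) - np.searchsorted(m, lo)
        span = np.maximum((hi - lo) - w, 1)
        lam_local = (local_k - k) / span * w
        lam_genome = rate * w
        lam = np.maximum(lam_local, lam_genome)
        if bg_mids is not None:
            bm = bg_mids.get(chrom, np.empty(0, dtype=np.int64))
            bk = np.searchsorted(bm, starts + w) - np.searchsorted(bm, starts)
            lam = np.maximum(lam, bk * depth_ratio)
        lam = np.maximum(lam, 1e-9)
        p = stats.poisson.sf(k - 1, lam)
        out[chrom] = {
            "starts": starts, "count": k.astype(np.int64),
            "lam": lam, "p": p, "fold": k / lam,
        }
    return out


def call_peaks(
    signal: FragmentSet,
    background: FragmentSet | None,
    genome: GenomeModel,
    params: PeakCallParams,
    sample_label: str = "",
) -> PeakSet:
    """Call fixed-width enrichment peaks.

    Candidates are scored genome-wide, q-values computed over all candidates by
    Benjamini-Hochberg, and survivors (q <= threshold, fold >= min_fold) selected
    greedily by ascending p (ties to the leftmost coordinate), rejecting any
    candidate whose center is within ``min_dist`` of an accepted one.
    """
    scored = score_windows(signal, background, genome, params)
    chroms, starts, counts, lams, ps, folds = [], [], [], [], [], []
    for chrom, d in scored.items():
        chroms.extend([chrom] * d["starts"].size)
        starts.append(d["starts"])
        counts.append(d["count"])
        lams.append(d["lam"])
        ps.append(d["p"])
        folds.append(d["fold"])
    if not starts:
        return PeakSet([], sample_label, params)
    starts = np.concatenate(starts)
    counts = np.concatenate(counts)
    lams = np.concatenate(lams)
    ps = np.concatenate(ps)
    folds = np.concatenate(folds)
    qs = bh_qvalues(ps)
    keep = (qs <= params.q_threshold) & (folds >= params.min_fold) & (counts > 0)
    idx = np.flatnonzero(keep)
    # greedy: ascending p, ties leftmost (chrom then start)
    order = sorted(idx, key=lambda i: (ps[i], chroms[i], starts[i]))
    accepted: list[int] = []
    centers_by_chrom: dict[str, list[int]] = {}
    w = params.window
    for i in order:
        c = chroms[i]
        center = int(starts[i]) + w // 2
        if any(abs(center - a) < params.min_dist for a in centers_by_chrom.get(c, [])):
            continue
        centers_by_chrom.setdefault(c, []).append(center)
        accepted.append(i)
    peaks = [
        Peak(chroms[i], int(starts[i]), int(starts[i]) + w,
             int(counts[i]), float(folds[i]), float(ps[i]), float(qs[i]))
        for i in accepted
    ]
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return PeakSet(peaks, sample_label, params)


def remove_blacklisted(peaks: PeakSet, blacklist: Iterable[Interval]) -> PeakSet:
    """Drop every peak sharing >=1 bp with a blacklist interval."""
    blk = list(blacklist)
    if not blk:
        return PeakSet(list(peaks.peaks), peaks.sample_label, peaks.params)
    index = intervals_by_chrom(blk)
    kept = [
        p for p in peaks.peaks
        if not overlaps_any(Interval(p.chrom, p.start, p.end), index)
    ]
    return PeakSet(kept, peaks.sample_label, peaks.params)


def broaden(
    peaks: PeakSet | Sequence[Interval],
    flank: int,
    genome: GenomeModel | None = None,
) -> list[Interval]:
    """Extend each peak by ``flank`` both sides, clip to the chromosome, merge."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    ivs = peaks.intervals() if isinstance(peaks, PeakSet) else list(peaks)
    grown = []
    for iv in ivs:
        start = max(0, iv.start - flank)
        end = iv.end + flank
        if genome is not None:
            end = min(end, genome.length(iv.chrom))
        grown.append(Interval(iv.chrom, start, end))
    return merge_intervals(grown)


@dataclass
class DifferentialParams:
    flank: int = 200          # broad-peak extension
    count_window: int = 200
    min_fold: float = 2.0
    p_threshold: float = 1e-4
    placement_step: int = 25

    def __post_init__(self) -> None:
        if self.min_fold < 1.0:
            raise ValueError("min_fold must be >= 1")


@dataclass(frozen=True)
class DifferentialPeak:
    chrom: str
    start: int
    end: int
    direction: str            # closed_in_target | opened_in_target
    fold: float
    p: float
    target_count: float       # depth-normalized
    control_count: float


@dataclass
class DifferentialPeakSet:
    peaks: list[DifferentialPeak]
    params: DifferentialParams

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def closed_in_target(self) -> list[DifferentialPeak]:
        return [p for p in self.peaks if p.direction == "closed_in_target"]

    def to_bed(self, path: str | Path) -> None:
        write_intervals(
            [
                Interval(p.chrom, p.start, p.end, score=p.fold, name=p.direction)
                for p in self.peaks
            ],
            path,
        )


def differential_peaks(
    target: FragmentSet,
    control: FragmentSet,
    candidates: Sequence[Interval],
    params: DifferentialParams,
) -> DifferentialPeakSet:
    """Two-condition differential accessibility over candidate (broad) regions.

    Counts are fragment midpoints in a ``count_window`` slid across each
    candidate; both libraries are scaled to the smaller depth. The placement
    with the smallest Poisson tail p (lambda = normalized control count,
    depletion or enrichment, whichever is stronger) represents the candidate;
    it is called when fold >= min_fold (with +1 pseudocounts) and
    p <= p_threshold. Direction follows the fold orientation.
    """
    if target.total_count == 0 or control.total_count == 0:
        raise ValueError("both fragment sets must be nonempty")
    scale = min(target.total_count, control.total_count)
    s_t = scale / target.total_count
    s_c = scale / control.total_count
    t_mids = target.midpoints()
    c_mids = control.midpoints()
    w = params.count_window
    out: list[DifferentialPeak] = []
    for cand in candidates:
        if cand.width <= w:
            placements = [cand.center - w // 2]
        else:
            placements = list(range(cand.start, cand.end - w + 1, params.placement_step))
            last = cand.end - w
            if placements[-1] != last:
                placements.append(last)
        tm = t_mids.get(cand.chrom, np.empty(0, dtype=np.int64))
        cm = c_mids.get(cand.chrom, np.empty(0, dtype=np.int64))
        best: tuple[float, int] | None = None  # (p, start) -- ties leftmost
        best_rec: DifferentialPeak | None = None
        for s in placements:
            kt = int(np.searchsorted(tm, s + w) - np.searchsorted(tm, s))
            kc = int(np.searchsorted(cm, s + w) - np.searchsorted(cm, s))
            nt, nc = kt * s_t, kc * s_c
            fold_closed = (nc + 1.0) / (nt + 1.0)
            fold_open = (nt + 1.0) / (nc + 1.0)
            lam = max(nc, 1e-9)
            if fold_closed >= fold_open:
                direction, fold = "closed_in_target", fold_closed
                p = float(stats.poisson.cdf(math.floor(nt), lam))
            else:
                direction, fold = "opened_in_target", fold_open
                p = float(stats.poisson.sf(math.ceil(nt) - 1, lam))
            key = (p, s)
            if best is None or key < best:
                best = key
                best_rec = DifferentialPeak(
                    cand.chrom, int(s), int(s) + w, direction,
                    float(fold), p, nt, nc,
                )
        assert best_rec is not None
        if best_rec.fold >= params.min_fold and best_rec.p <= params.p_threshold:
            out.append(best_rec)
    return DifferentialPeakSet(out, params)
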