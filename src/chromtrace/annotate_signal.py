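"""TSS annotation, signal matrices and region-class signal summaries.

Regions are linked to their nearest transcription start site (promoter-proximal
= within +/-3 kb by default), signal tracks are summarized in centered
fixed-bin windows (heatmap/aggregation matrices, rows sorted by the first
sample's mean), and per-class signal distributions and peak-gene overlap
counts are computed for downstream comparison.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import CoverageTrack, Interval
from .region_classes import LABELS, RegionClassTable


class TSSTable:
    """Transcription start sites: (gene, chrom, pos, strand), unique gene names."""

    def __init__(self, entries: Iterable[tuple[str, str, int, str]]) -> None:
        self.df = pd.DataFrame(entries, columns=["gene", "chrom", "pos", "strand"])
        if self.df["gene"].duplicated().any():
            dup = self.df.loc[self.df["gene"].duplicated(), "gene"].iloc[0]
            raise ValueError(f"duplicate gene name {dup!r}")
        self._by_chrom: dict[str, pd.DataFrame] = {}
        for chrom, sub in self.df.groupby("chrom"):
            sub = sub.sort_values(["pos", "gene"], kind="stable").reset_index(drop=True)
            self._by_chrom[chrom] = sub

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_names(self) -> set[str]:
        return set(self.df["gene"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TSSTable":
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            gene, chrom, pos, strand = line.split("\t")[:4]
            rows.append((gene, chrom, int(pos), strand))
        return cls(rows)

    @classmethod
    def from_bed(cls, path: str | Path) -> "TSSTable":
        """BED6 where the TSS is the strand-aware 5' end of each record."""
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}"
            strand = parts[5] if len(parts) > 5 else "+"
            pos = start if strand != "-" else end - 1
            rows.append((name, chrom, pos, strand))
        return cls(rows)


def annotate_nearest_tss(
    regions: Sequence[Interval],
    tss: TSSTable,
    promoter_flank: int = 3000,
) -> pd.DataFrame:
    """Nearest-TSS assignment per region.

    Distance is region center minus TSS position (chromosome orientation; gene
    strand is recorded but not applied to the sign). Ties go to the
    lexicographically smaller gene name. Regions on chromosomes without any
    TSS are left unannotated (NaN) with a warning.
    """
    if len(tss) == 0:
        raise ValueError("TSS table is empty")
    rows = []
    n_unannotated = 0
    for r in regions:
        sub = tss._by_chrom.get(r.chrom)
        if sub is None:
            n_unannotated += 1
            rows.append((r.chrom, r.start, r.end, None, np.nan, False, "."))
            continue
        pos = sub["pos"].to_numpy()
        c = r.center
        i = int(np.searchsorted(pos, c))
        cands: list[tuple[int, str, str]] = []  # (|dist|, gene, strand)
        for j in (i - 1, i):
            if 0 <= j < len(sub):
                cands.append(
                    (abs(c - int(pos[j])), sub["gene"].iloc[j], sub["strand"].iloc[j])
                )
        # include neighbors at duplicated positions so name tie-break is exact
        best_d = min(d for d, _, _ in cands)
        lo_j, hi_j = max(0, i - 1), min(len(sub), i + 1)
        while lo_j - 1 >= 0 and abs(c - int(pos[lo_j - 1])) == best_d:
            lo_j -= 1
        while hi_j < len(sub) and abs(c - int(pos[hi_j])) == best_d:
            hi_j += 1
        ties = [
            (abs(c - int(pos[j])), sub["gene"].iloc[j], sub["strand"].iloc[j])
            for j in range(lo_j, hi_j)
            if abs(c - int(pos[j])) == best_d
        ]
        _, gene, strand = min(ties, key=lambda t: t[1])
        signed = c - int(sub.loc[sub["gene"] == gene, "pos"].iloc[0])
        rows.append(
            (r.chrom, r.start, r.end, gene, signed, abs(signed) <= promoter_flank, strand)
        )
    if n_unannotated:
        warnings.warn(f"{n_unannotated} regions on chromosomes without any TSS")
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "gene", "distance", "promoter_proximal", "tss_strand"],
    )


@dataclass
class MatrixParams:
    flank: int = 2000       # bp each side of the region center
    bin: int = 10
    center_mode: str = "region_center"

    def __post_init__(self) -> None:
        if self.flank % self.bin != 0:
            raise ValueError("flank must be divisible by bin")
        if self.center_mode not in ("region_center", "summit"):
            raise ValueError(f"unknown center_mode {self.center_mode!r}")


@dataclass
class SignalMatrix:
    """Region x bin signal matrices for one or more samples, jointly row-sorted.

    ``matrices[k][i, j]`` is sample k's mean signal in bin j of the window
    centered on region ``row_order[i]``; rows are ordered by descending
    per-row mean of the FIRST sample, and that order is applied to all
    samples. Cells whose window runs off the chromosome are NaN and excluded
    from row means and column profiles.
    """

    matrices: list[np.ndarray]
    row_order: np.ndarray          # indices into the input region list
    params: MatrixParams
    n_regions: int = 0

    @property
    def n_bins(self) -> int:
        return 2 * self.params.flank // self.params.bin

    def profile(self, k: int = 0) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.matrices[k], axis=0)

    def to_tsv(self, path: str | Path, labels: Sequence[str] | None = None) -> None:
        header = {
            "flank": self.params.flank,
            "bin": self.params.bin,
            "n_regions": self.n_regions,
            "samples": list(labels) if labels else list(range(len(self.matrices))),
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
            for k, mat in enumerate(self.matrices):
                for i in range(mat.shape[0]):
                    vals = "\t".join(f"{v:.6g}" for v in mat[i])
                    fh.write(f"{k}\t{self.row_order[i]}\t{vals}\n")


def signal_matrix(
    tracks: CoverageTrack | Sequence[CoverageTrack],
    regions: Sequence[Interval],
    params: MatrixParams,
) -> SignalMatrix:
    """deepTools-style matrix: per region, mean signal in each bin of the
    window [center - flank, center + flank); rows sorted by the first track."""
    if isinstance(tracks, CoverageTrack):
        tracks = [tracks]
    if not regions:
        raise ValueError("no regions")
    n_bins = 2 * params.flank // params.bin
    mats = []
    for track in tracks:
        if track.bin != 1:
            raise ValueError("per-bp (bin=1) tracks required")
        mat = np.full((len(regions), n_bins), np.nan)
        for i, r in enumerate(regions):
            if r.chrom not in track.data:
                continue
            arr = track.data[r.chrom]
            L = arr.size
            w_start = r.center - params.flank
            for j in range(n_bins):
                s = w_start + j * params.bin
                e = s + params.bin
                if s < 0 or e > L:
                    continue  # off-chromosome bins stay NaN
                mat[i, j] = arr[s:e].mean()
        mats.append(mat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_mean = np.nanmean(mats[0], axis=1)
    row_mean = np.where(np.isnan(row_mean), -np.inf, row_mean)
    order = np.argsort(-row_mean, kind="stable")
    return SignalMatrix(
        [m[order] for m in mats], order, params, n_regions=len(regions)
    )


def regionclass_signal_summary(
    track: CoverageTrack,
    classes: RegionClassTable,
    bin: int = 1000,
) -> pd.DataFrame:
    """Mean signal in the ``bin`` bp window centered on each region, summarized
    per class (n, mean, quartiles). Invariant to region input order."""
    if len(classes) == 0:
        raise ValueError("empty region class table")
    per_region = []
    for r, lab in zip(classes.regions, classes.labels):
        c = r.center
        s = max(0, c - bin // 2)
        e = min(track.chrom_lengths[r.chrom], c + bin // 2)
        per_region.append((lab, track.data[r.chrom][s:e].mean()))
    df = pd.DataFrame(per_region, columns=["label", "mean_signal"])
    out = (
        df.groupby("label")["mean_signal"]
        .agg(
            n="count",
            mean="mean",
            q1=lambda v: v.quantile(0.25),
            median="median",
            q3=lambda v: v.quantile(0.75),
        )
        .reset_index()
    )
    return out


def peak_gene_overlap_counts(
    regions: Sequence[Interval],
    tss: TSSTable,
    gene_lists: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Overlap between region-associated genes (nearest TSS) and named gene lists.

    Returns per list: the overlap count, the fraction of the list covered, and
    a tally of list names absent from the TSS table's namespace.
    """
    ann = annotate_nearest_tss(regions, tss)
    associated = set(ann["gene"].dropna())
    namespace = tss.gene_names
    rows = []
    for name, genes in gene_lists.items():
        genes = list(genes)
        if not genes:
            warnings.warn(f"gene list {name!r} is empty")
            rows.append((name, 0, 0, np.nan, 0))
            continue
        mismatches = sum(1 for g in genes if g not in namespace)
        hit = sum(1 for g in set(genes) if g in associated)
        rows.append((name, len(genes), hit, hit / len(genes), mismatches))
    return pd.DataFrame(
        rows, columns=["gene_list", "n_genes", "overlap_count", "fraction", "namespace_mismatches"]
    )
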