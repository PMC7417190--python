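"""Two-factor peak-overlap classification.

Peak sets for two factors (A and B) are combined, overlapping peaks merged, and
each merged region labeled A_only, B_only or AB_overlap by which source sets it
intersects. Venn-style counts are reported both in merged-region units and in
source-peak units, since the two conventions genuinely differ whenever one
peak spans several peaks of the other set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genome_io import Interval, intervals_by_chrom, merge_intervals, overlaps_any
from .peaks import PeakSet

LABELS = ("A_only", "B_only", "AB_overlap")


def _as_intervals(peaks: PeakSet | Sequence[Interval]) -> list[Interval]:
    return peaks.intervals() if isinstance(peaks, PeakSet) else list(peaks)


@dataclass
class RegionClassTable:
    regions: list[Interval]          # merged A union B regions, sorted
    labels: list[str]                # one of LABELS per region
    label_A: str = "A"
    label_B: str = "B"

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.labels):
            raise ValueError("regions and labels must align")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {bad}")

    @property
    def counts(self) -> dict[str, int]:
        return {lab: self.labels.count(lab) for lab in LABELS}

    def by_class(self, label: str) -> list[Interval]:
        return [r for r, l in zip(self.regions, self.labels) if l == label]

    def __len__(self) -> int:
        return len(self.regions)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r, lab in zip(self.regions, self.labels):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{lab}\t0\t.\n")


def classify_regions(
    peaks_A: PeakSet | Sequence[Interval],
    peaks_B: PeakSet | Sequence[Interval],
    label_A: str = "A",
    label_B: str = "B",
) -> RegionClassTable:
    """Merge the union of both peak sets and label each merged region.

    A region is AB_overlap iff it intersects >=1 peak from each set (>=1 bp);
    A_only iff it intersects A but not B; B_only otherwise. The labels
    partition the merged regions.
    """
    a = _as_intervals(peaks_A)
    b = _as_intervals(peaks_B)
    merged = merge_intervals(a + b)
    idx_a = intervals_by_chrom(a) if a else {}
    idx_b = intervals_by_chrom(b) if b else {}
    labels = []
    for r in merged:
        in_a = overlaps_any(r, idx_a)
        in_b = overlaps_any(r, idx_b)
        labels.append("AB_overlap" if (in_a and in_b) else ("A_only" if in_a else "B_only"))
    return RegionClassTable(merged, labels, label_A, label_B)


@dataclass(frozen=True)
class VennCounts:
    """Overlap cardinalities in both source-peak and merged-region units.

    Source-peak units: a peak counts as overlapping if it intersects >=1 peak of
    the other set (one A peak spanning two B peaks contributes 1 to a_overlap
    while the two B peaks contribute 2 to b_overlap). Merged-region units are
    the class counts of :func:`classify_regions`.
    """

    a_only: int
    b_only: int
    a_overlap: int
    b_overlap: int
    region_a_only: int
    region_b_only: int
    region_overlap: int

    def peak_units(self) -> dict[str, int]:
        return {
            "a_only": self.a_only, "a_overlap": self.a_overlap,
            "b_overlap": self.b_overlap, "b_only": self.b_only,
        }

    def region_triple(self) -> tuple[int, int, int]:
        return (self.region_a_only, self.region_overlap, self.region_b_only)


def overlap_venn(
    peaks_A: PeakSet | Sequence[Interval],
    peaks_B: PeakSet | Sequence[Interval],
) -> VennCounts:
    a = _as_intervals(peaks_A)
    b = _as_intervals(peaks_B)
    idx_a = intervals_by_chrom(a) if a else {}
    idx_b = intervals_by_chrom(b) if b else {}
    a_ov = sum(1 for iv in a if overlaps_any(iv, idx_b))
    b_ov = sum(1 for iv in b if overlaps_any(iv, idx_a))
    table = classify_regions(a, b)
    c = table.counts
    return VennCounts(
        a_only=len(a) - a_ov,
        b_only=len(b) - b_ov,
        a_overlap=a_ov,
        b_overlap=b_ov,
        region_a_only=c["A_only"],
        region_b_only=c["B_only"],
        region_overlap=c["AB_overlap"],
    )


def motif_fraction(
    regions: RegionClassTable | PeakSet | Sequence[Interval],
    matches: Iterable[Interval],
) -> dict[str, float | None] | float | None:
    """Fraction of regions containing >=1 motif match (any strand).

    For a :class:`RegionClassTable`, one fraction per class; a class with no
    regions reports ``None`` (undefined), never 0.
    """
    idx = intervals_by_chrom(list(matches))

    def frac(ivs: Sequence[Interval]) -> float | None:
        if not ivs:
            return None
        return sum(1 for r in ivs if overlaps_any(r, idx)) / len(ivs)

    if isinstance(regions, RegionClassTable):
        return {lab: frac(regions.by_class(lab)) for lab in LABELS}
    return frac(_as_intervals(regions))


def write_summary(
    table: RegionClassTable,
    venn: VennCounts,
    path: str | Path,
    fractions: Mapping[str, float | None] | None = None,
) -> None:
    payload = {
        "counts": table.counts,
        "venn_peak_units": venn.peak_units(),
        "venn_region_units": dict(
            zip(("A_only", "AB_overlap", "B_only"), venn.region_triple())
        ),
    }
    if fractions is not None:
        payload["motif_fraction"] = dict(fractions)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
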