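"""Coordinate types and readers/writers for the interval/coverage formats the pipeline touches.

All coordinates are 0-based half-open (BED convention) internally. Supported
formats: BED3/BED6, bedGraph, FASTA (genome sequence), two-column chrom-sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """Raised when an input file line cannot be parsed."""


@dataclass(frozen=True)
class Interval:
    """A genomic region, 0-based half-open: bases [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        # even widths round down: center of [0, 10) is 5
        return self.start + self.width // 2

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def shifted(self, delta: int) -> "Interval":
        return replace(self, start=self.start + delta, end=self.end + delta)


class GenomeModel:
    """Chromosome names, lengths and (optionally) nucleotide sequence.

    Any genome can stand behind the coordinates; the pipeline never assumes a
    particular assembly. Sequence, when present, is an upper-case A/C/G/T/N
    string per chromosome whose length equals the declared length.
    """

    def __init__(
        self,
        chrom_lengths: Mapping[str, int],
        sequence: Mapping[str, str] | None = None,
    ) -> None:
        names = list(chrom_lengths)
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths)
        self.sequence: dict[str, str] | None = None
        if sequence is not None:
            seqs = {}
            for name in names:
                if name not in sequence:
                    raise ValueError(f"sequence missing for chromosome {name}")
                s = sequence[name].upper()
                if len(s) != self.chrom_lengths[name]:
                    raise ValueError(
                        f"sequence length {len(s)} != declared length "
                        f"{self.chrom_lengths[name]} for {name}"
                    )
                seqs[name] = s
            self.sequence = seqs

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]

    def contains(self, iv: Interval) -> bool:
        return iv.chrom in self.chrom_lengths and iv.end <= self.chrom_lengths[iv.chrom]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeModel":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ParseError(f"no sequences in {path}")
        return cls({k: len(v) for k, v in seqs.items()}, seqs)

    def to_fasta(self, path: str | Path) -> None:
        if self.sequence is None:
            raise ValueError("genome has no sequence")
        records = [
            SeqRecord(Seq(self.sequence[name]), id=name, description="")
            for name in self.chrom_names
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeModel":
        lengths: dict[str, int] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}: line {i}: expected 2 tab-separated columns")
            lengths[parts[0]] = int(parts[1])
        return cls(lengths)

    def to_chrom_sizes(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{n}\t{l}\n" for n, l in self.chrom_lengths.items())
        )


class FragmentSet:
    """A set of sequenced fragment intervals (the unit ATAC/ChIP signal is built from)."""

    def __init__(self, fragments: Iterable[Interval], paired: bool = True) -> None:
        self.fragments: list[Interval] = list(fragments)
        self.paired = paired
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def total_count(self) -> int:
        return len(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.fragments)

    def validate(self, genome: GenomeModel) -> None:
        for f in self.fragments:
            if not genome.contains(f):
                raise ValueError(f"fragment {f.chrom}:{f.start}-{f.end} outside genome")

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """(starts, ends) arrays per chromosome, sorted by start. Cached."""
        if self._by_chrom is None:
            buckets: dict[str, list[tuple[int, int]]] = {}
            for f in self.fragments:
                buckets.setdefault(f.chrom, []).append((f.start, f.end))
            out = {}
            for chrom, pairs in buckets.items():
                arr = np.asarray(sorted(pairs), dtype=np.int64)
                out[chrom] = (arr[:, 0], arr[:, 1])
            self._by_chrom = out
        return self._by_chrom

    def midpoints(self) -> dict[str, np.ndarray]:
        """Sorted fragment midpoint coordinates per chromosome."""
        out = {}
        for chrom, (s, e) in self.by_chrom().items():
            out[chrom] = np.sort((s + e) // 2)
        return out

    def lengths(self) -> np.ndarray:
        return np.asarray([f.width for f in self.fragments], dtype=np.int64)

    def concat(self, other: "FragmentSet") -> "FragmentSet":
        return FragmentSet(self.fragments + other.fragments, paired=self.paired and other.paired)

    @classmethod
    def from_bed(cls, path: str | Path, paired: bool = True) -> "FragmentSet":
        return cls(read_intervals(path), paired=paired)

    def to_bed(self, path: str | Path) -> None:
        write_intervals(self.fragments, path)


class CoverageTrack:
    """Per-chromosome signal arrays at a fixed bin resolution.

    ``data[chrom][i]`` covers bases ``[i*bin, (i+1)*bin)``; array length is
    ``ceil(chrom_length / bin)``. ``tag`` records the normalization state.
    """

    VALID_TAGS = ("raw", "RPM", "RPKM", "normalized")

    def __init__(
        self,
        data: Mapping[str, np.ndarray],
        chrom_lengths: Mapping[str, int],
        bin: int = 1,
        tag: str = "raw",
    ) -> None:
        if tag not in self.VALID_TAGS:
            raise ValueError(f"unknown tag {tag!r}")
        if bin < 1:
            raise ValueError("bin must be >= 1")
        self.bin = bin
        self.tag = tag
        self.chrom_lengths = dict(chrom_lengths)
        self.data: dict[str, np.ndarray] = {}
        for chrom, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            expected = math.ceil(self.chrom_lengths[chrom] / bin)
            if arr.shape != (expected,):
                raise ValueError(
                    f"{chrom}: array length {arr.shape} != ceil(length/bin) = {expected}"
                )
            if tag != "normalized" and np.any(arr[np.isfinite(arr)] < 0):
                raise ValueError(f"{chrom}: negative values in a {tag} track")
            self.data[chrom] = arr

    @classmethod
    def zeros(cls, genome: GenomeModel, bin: int = 1, tag: str = "raw") -> "CoverageTrack":
        data = {
            c: np.zeros(math.ceil(l / bin)) for c, l in genome.chrom_lengths.items()
        }
        return cls(data, genome.chrom_lengths, bin=bin, tag=tag)

    @property
    def chrom_names(self) -> list[str]:
        return list(self.data)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Track values for bins overlapping [start, end); bin resolution only."""
        b = self.bin
        return self.data[chrom][start // b : math.ceil(end / b)]

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        v = self.values(chrom, max(start, 0), min(end, self.chrom_lengths[chrom]))
        return float(np.mean(v)) if v.size else float("nan")


def read_intervals(path: str | Path, format: str = "BED") -> list[Interval]:
    """Parse a BED (>=3 columns) or bedGraph-region (4 columns, score) file.

    Comment (#), ``track`` and ``browser`` lines are skipped; record order is
    preserved. Malformed lines raise :class:`ParseError` naming the line.
    """
    if format not in ("BED", "bedGraph-region"):
        raise ValueError(f"unknown format {format!r}")
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            score: float | None = None
            name: str | None = None
            strand = "."
            if format == "bedGraph-region":
                if len(parts) < 4:
                    raise ParseError(f"{path}: line {lineno}: bedGraph needs 4 columns")
                score = float(parts[3])
            else:
                if len(parts) >= 4 and parts[3] not in ("", "."):
                    name = parts[3]
                if len(parts) >= 5 and parts[4] not in ("", "."):
                    try:
                        score = float(parts[4])
                    except ValueError:
                        score = None
                if len(parts) >= 6 and parts[5] in ("+", "-", "."):
                    strand = parts[5]
            try:
                out.append(Interval(chrom, start, end, score=score, name=name, strand=strand))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return out


def filter_to_genome(
    intervals: Iterable[Interval], genome: GenomeModel
) -> list[Interval]:
    """Drop intervals on chromosomes absent from the genome model (with a warning)."""
    kept, dropped = [], 0
    for iv in intervals:
        if iv.chrom in genome.chrom_lengths:
            kept.append(iv)
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} intervals on unknown chromosomes")
    return kept


def write_intervals(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write intervals as BED6 (name/score/strand filled with defaults)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = 0.0 if iv.score is None else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score:.6g}\t{iv.strand}\n"
            )


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph, run-length collapsing equal adjacent values.

    Zero-valued runs are omitted (bedGraph convention: unreported = 0).
    Values are printed with 6 significant digits. NaN raises, naming the
    offending position.
    """
    with open(path, "w") as fh:
        for chrom, arr in track.data.items():
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise ValueError(
                    f"non-finite value at {chrom} bin {bad[0]} "
                    f"(base {bad[0] * track.bin})"
                )
            if arr.size == 0:
                continue
            # run-length boundaries
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            length = track.chrom_lengths[chrom]
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0.0:
                    continue
                fh.write(
                    f"{chrom}\t{s * track.bin}\t{min(e * track.bin, length)}\t{v:.6g}\n"
                )


def read_bedgraph(
    path: str | Path, genome: GenomeModel, bin: int = 1, tag: str = "raw"
) -> CoverageTrack:
    """Read a bedGraph file into a track at the given bin resolution.

    Record boundaries must fall on bin boundaries (except a final partial bin).
    """
    track = CoverageTrack.zeros(genome, bin=bin, tag=tag)
    for iv in read_intervals(path, format="bedGraph-region"):
        if iv.chrom not in track.data:
            warnings.warn(f"bedGraph record on unknown chromosome {iv.chrom}; dropped")
            continue
        if iv.start % bin != 0:
            raise ParseError(f"record start {iv.start} not on a {bin} bp bin boundary")
        track.data[iv.chrom][iv.start // bin : math.ceil(iv.end / bin)] = iv.score
    return track


def coverage_from_fragments(
    frags: FragmentSet, genome: GenomeModel, bin: int = 1
) -> CoverageTrack:
    """Depth-normalized per-base coverage: RPM = overlap count x 1e6 / total fragments.

    With ``bin > 1`` each bin holds the mean of its constituent bases (the last,
    possibly partial, bin averages over the bases it actually covers).
    """
    if frags.total_count == 0:
        raise ValueError("RPM undefined for an empty fragment set")
    scale = 1e6 / frags.total_count
    data: dict[str, np.ndarray] = {}
    by_chrom = frags.by_chrom()
    for chrom, length in genome.chrom_lengths.items():
        diff = np.zeros(length + 1)
        if chrom in by_chrom:
            s, e = by_chrom[chrom]
            np.add.at(diff, np.clip(s, 0, length), 1.0)
            np.add.at(diff, np.clip(e, 0, length), -1.0)
        per_bp = np.cumsum(diff[:-1]) * scale
        if bin == 1:
            data[chrom] = per_bp
        else:
            n_bins = math.ceil(length / bin)
            edges = np.arange(n_bins) * bin
            sums = np.add.reduceat(per_bp, edges)
            widths = np.minimum(edges + bin, length) - edges
            data[chrom] = sums / widths
    return CoverageTrack(data, genome.chrom_lengths, bin=bin, tag="RPM")


def merge_intervals(xs: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping and touching intervals; output sorted and disjoint."""
    by_chrom: dict[str, list[Interval]] = {}
    for iv in xs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # touching merges
                cur_e = max(cur_e, iv.end)
            else:
                out.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(Interval(chrom, cur_s, cur_e))
    return out


def intervals_by_chrom(xs: Iterable[Interval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sorted, merged (starts, ends) arrays per chromosome, for overlap queries."""
    merged = merge_intervals(xs)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in merged:
        out.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
    for chrom in out:
        ivs = [iv for iv in merged if iv.chrom == chrom]
        out[chrom] = (
            np.asarray([iv.start for iv in ivs], dtype=np.int64),
            np.asarray([iv.end for iv in ivs], dtype=np.int64),
        )
    return out


def overlaps_any(iv: Interval, index: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> bool:
    """True iff interval shares >=1 bp with a merged, sorted interval set."""
    if iv.chrom not in index:
        return False
    starts, ends = index[iv.chrom]
    i = int(np.searchsorted(ends, iv.start, side="right"))
    return bool(i < len(starts) and starts[i] < iv.end)


def contained_in_any(
    chrom: str, start: int, end: int, index: Mapping[str, tuple[np.ndarray, np.ndarray]]
) -> bool:
    """True iff [start, end) lies entirely inside one merged interval."""
    if chrom not in index:
        return False
    starts, ends = index[chrom]
    i = int(np.searchsorted(starts, start, side="right")) - 1
    return bool(i >= 0 and ends[i] >= end)
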