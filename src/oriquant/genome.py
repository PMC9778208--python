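"""Genome model, binned signal tracks, and text-format I/O.

All coordinates are 0-based, half-open (BED convention). Signal tracks are
stored at fixed bin width (default 50 bp, the resolution used throughout the
pipeline); bin ``i`` of a chromosome covers base pairs ``[i*w, (i+1)*w)``,
with the last bin truncated at the chromosome end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomeBuild",
    "GenomicInterval",
    "BinnedTrack",
    "read_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed_features",
    "write_bed_features",
]


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes with their lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeBuild":
        return cls(tuple(sizes), tuple(sizes.values()))

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str, bin_width: int) -> int:
        return math.ceil(self.length_of(chrom) / bin_width)

    def bin_widths(self, chrom: str, bin_width: int) -> np.ndarray:
        """True bp width of each bin (last bin may be truncated)."""
        n = self.n_bins(chrom, bin_width)
        widths = np.full(n, float(bin_width))
        widths[-1] = self.length_of(chrom) - (n - 1) * bin_width
        return widths


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, optionally named/stranded."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None
    attrs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def validate(self, genome: GenomeBuild) -> "GenomicInterval":
        if self.end > genome.length_of(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {genome.length_of(self.chrom)}"
            )
        return self


@dataclass
class BinnedTrack:
    """Fixed-bin-width, per-chromosome signal vectors over a genome."""

    genome: GenomeBuild
    bin_width: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def zeros(cls, genome: GenomeBuild, bin_width: int = 50) -> "BinnedTrack":
        values = {
            c: np.zeros(genome.n_bins(c, bin_width)) for c in genome.chrom_names
        }
        return cls(genome, bin_width, values)

    def validate(self) -> "BinnedTrack":
        for chrom in self.genome.chrom_names:
            v = self.values.get(chrom)
            if v is None:
                raise ValueError(f"missing values for chromosome {chrom}")
            n = self.genome.n_bins(chrom, self.bin_width)
            if len(v) != n:
                raise ValueError(
                    f"{chrom}: expected {n} bins, found {len(v)}"
                )
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{chrom}: non-finite bin values")
        return self

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            self.genome, self.bin_width, {c: v.copy() for c, v in self.values.items()}
        )

    def concatenated(self) -> np.ndarray:
        """All bin values, chromosomes in genome order."""
        return np.concatenate([self.values[c] for c in self.genome.chrom_names])

    def total(self) -> float:
        """Genome-wide sum of bin values (the scale-normalization statistic)."""
        return float(sum(v.sum() for v in self.values.values()))

    def mass(self) -> float:
        """Genome-wide sum of value x bin-bp (conserved by binning)."""
        return float(
            sum(
                (v * self.genome.bin_widths(c, self.bin_width)).sum()
                for c, v in self.values.items()
            )
        )

    def same_shape_as(self, other: "BinnedTrack") -> bool:
        return (
            self.genome == other.genome
            and self.bin_width == other.bin_width
        )


def read_chrom_sizes(path: str | Path) -> GenomeBuild:
    """Read a UCSC-style chrom.sizes table (name, length)."""
    names: list[str] = []
    lengths: list[int] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: malformed line {line!r}")
        name = parts[0]
        try:
            length = int(parts[1])
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: non-integer length {parts[1]!r}"
            ) from None
        if name in names:
            raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
        if length <= 0:
            raise ValueError(f"{path}:{lineno}: non-positive length for {name}")
        names.append(name)
        lengths.append(length)
    if not names:
        raise ValueError(f"{path}: no chromosomes")
    return GenomeBuild(tuple(names), tuple(lengths))


def read_bedgraph(
    path: str | Path, genome: GenomeBuild, bin_width: int = 50
) -> BinnedTrack:
    """Read a bedGraph into a binned track.

    Each record's value is distributed to bins by bp overlap; each bin's
    value is the per-bp mean of record values over the bin, with uncovered
    base pairs counting as zero (so an exactly tiled constant bedGraph
    round-trips exactly). Coverage-like values must be non-negative.
    """
    track = BinnedTrack.zeros(genome, bin_width)
    acc = {c: np.zeros_like(v) for c, v in track.values.items()}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: malformed bedGraph line")
        chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if chrom not in genome.lengths:
            raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if not 0 <= start < end <= genome.length_of(chrom):
            raise ValueError(
                f"{path}:{lineno}: interval {start}-{end} invalid for {chrom}"
            )
        if value < 0:
            raise ValueError(
                f"{path}:{lineno}: negative coverage value {value}"
            )
        _accumulate_overlap(
            acc[chrom], start, end, value, bin_width,
            genome.bin_widths(chrom, bin_width),
        )
    track.values = acc
    return track.validate()


def _accumulate_overlap(
    acc: np.ndarray, start: int, end: int, value: float, w: int,
    widths: np.ndarray,
) -> None:
    """Add value x (bp-overlap / bin width) to each touched bin.

    Fully covered bins receive exactly ``value`` (overlap fraction 1.0), so
    tiled bedGraphs round-trip bit-exactly through write_bedgraph.
    """
    i0, i1 = start // w, (end - 1) // w
    if i0 == i1:
        acc[i0] += value * ((end - start) / widths[i0])
        return
    acc[i0] += value * (((i0 + 1) * w - start) / widths[i0])
    acc[i1] += value * ((end - i1 * w) / widths[i1])
    if i1 > i0 + 1:
        acc[i0 + 1 : i1] += value


def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    """Write one record per maximal run of equal-valued bins.

    Zero-valued runs are written explicitly so the file tiles the genome and
    ``read_bedgraph(write_bedgraph(t))`` reproduces bin values bit-exactly.
    """
    track.validate()
    w = track.bin_width
    with open(path, "w", newline="\n") as fh:
        for chrom in track.genome.chrom_names:
            v = track.values[chrom]
            length = track.genome.length_of(chrom)
            # run boundaries between unequal neighbours
            change = np.flatnonzero(v[1:] != v[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                fh.write(
                    f"{chrom}\t{s * w}\t{min(e * w, length)}\t{float(v[s])!r}\n"
                )


def read_bed_features(
    path: str | Path, genome: GenomeBuild
) -> list[GenomicInterval]:
    """Read BED3+ features; column 4 is the name, 6 the strand if present."""
    feats: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        name = parts[3] if len(parts) > 3 else None
        strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else None
        try:
            iv = GenomicInterval(
                chrom, start, end, name=name, strand=strand,
                attrs=tuple(parts[4:]),
            ).validate(genome)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        feats.append(iv)
    return feats


def write_bed_features(
    feats: Iterable[GenomicInterval], path: str | Path
) -> None:
    with open(path, "w", newline="\n") as fh:
        for iv in feats:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")
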