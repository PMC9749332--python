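"""Genomic coordinate frame: autosomes, centromeres, arms, and SNP marker maps.

All coordinates in this package are 0-based, half-open ``[start, end)`` base
pairs, so interval length is always ``end - start``.  Only autosomes are
modelled; sex chromosomes are out of scope.

A :class:`GenomeBuild` carries per-chromosome lengths and centromere
intervals; it is the coordinate frame every segment table is validated
against.  A :class:`MarkerMap` is the assay abstraction: a sorted table of
SNP marker positions with a per-marker GC fraction (GC content of a fixed
window around the marker, attached at map construction so that no reference
sequence is ever needed).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Chromosome",
    "GenomeBuild",
    "MarkerMap",
    "make_toy_build",
    "make_marker_map",
    "split_at_centromere",
]

#: fixed centromere width used by toy builds, bp
TOY_CENTROMERE_WIDTH = 3_000_000


@dataclass(frozen=True)
class Chromosome:
    """One autosome: total length and centromere interval (bp, half-open)."""

    name: str
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: non-positive length {self.length}")
        if not (0 < self.cen_start < self.cen_end < self.length):
            raise ValueError(
                f"{self.name}: centromere [{self.cen_start}, {self.cen_end}) must lie "
                f"strictly inside (0, {self.length})"
            )

    @property
    def arms(self) -> tuple[tuple[int, int, str], ...]:
        """The p and q arm intervals, excluding the centromere."""
        return ((0, self.cen_start, "p"), (self.cen_end, self.length, "q"))


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered collection of autosomes defining the coordinate frame."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names in build")
        if not self.chromosomes:
            raise ValueError("build must contain at least one chromosome")

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [c.name for c in self.chromosomes],
                "length": [c.length for c in self.chromosomes],
                "cen_start": [c.cen_start for c in self.chromosomes],
                "cen_end": [c.cen_end for c in self.chromosomes],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenomeBuild":
        required = {"chrom", "length", "cen_start", "cen_end"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"build table missing columns: {sorted(missing)}")
        chroms = tuple(
            Chromosome(str(r.chrom), int(r.length), int(r.cen_start), int(r.cen_end))
            for r in frame.itertuples()
        )
        return cls(chroms)

    @classmethod
    def hg19(cls) -> "GenomeBuild":
        """Bundled hg19-like table: 22 autosome lengths + centromere intervals."""
        ref = importlib.resources.files("hrdscan.data") / "hg19_autosomes.tsv"
        with importlib.resources.as_file(ref) as path:
            frame = pd.read_csv(path, sep="\t")
        return cls.from_frame(frame)


def make_toy_build(
    n_chrom: int,
    chrom_length: float,
    centromere_frac: float,
    cen_width: int = TOY_CENTROMERE_WIDTH,
) -> GenomeBuild:
    """Equal-length toy build with the centromere centred at ``centromere_frac``.

    The centromere has fixed width ``cen_width`` (default 3 Mb), clipped to lie
    strictly inside the chromosome.
    """
    if n_chrom < 1:
        raise ValueError(f"n_chrom must be >= 1, got {n_chrom}")
    if chrom_length <= 0:
        raise ValueError(f"chrom_length must be positive, got {chrom_length}")
    if not 0 < centromere_frac < 1:
        raise ValueError(f"centromere_frac must be in (0, 1), got {centromere_frac}")
    length = int(chrom_length)
    centre = centromere_frac * length
    cs = int(max(1, min(length - 1 - cen_width, centre - cen_width / 2)))
    ce = int(min(length - 1, cs + cen_width))
    chroms = tuple(Chromosome(f"chr{i + 1}", length, cs, ce) for i in range(n_chrom))
    return GenomeBuild(chroms)


@dataclass(frozen=True)
class MarkerMap:
    """Sorted SNP marker table: columns chrom, pos (bp), gc (fraction in [0,1])."""

    platform_name: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        required = {"chrom", "pos", "gc"}
        missing = required - set(f.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        gc = f["gc"].to_numpy()
        if np.any((gc < 0) | (gc > 1)):
            raise ValueError("gc fraction outside [0, 1]")
        for _, grp in f.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("marker positions must be strictly increasing per chromosome")

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    def validate_against(self, build: GenomeBuild) -> None:
        for chrom, grp in self.frame.groupby("chrom", sort=False):
            limit = build[str(chrom)].length
            pos = grp["pos"].to_numpy()
            if pos.min() < 0 or pos.max() >= limit:
                raise ValueError(f"{chrom}: marker position outside [0, {limit})")


def _gc_landscape(pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth synthetic GC landscape: a low-frequency sinusoid mixture.

    Periods of ~37 Mb and ~7 Mb with random phases give broad waves plus local
    texture, centred on a genome-typical GC of 0.42.
    """
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    gc = (
        0.42
        + 0.06 * np.sin(2 * np.pi * pos / 37e6 + phase1)
        + 0.03 * np.sin(2 * np.pi * pos / 7.1e6 + phase2)
    )
    return np.clip(gc, 0.0, 1.0)


def make_marker_map(
    build: GenomeBuild,
    n_markers: int,
    seed: int,
    platform_name: str = "synthetic",
) -> MarkerMap:
    """Place ``n_markers`` unique markers, allocated to chromosomes by length.

    Positions are uniform random within each chromosome (collisions redrawn);
    GC fractions come from a seeded smooth landscape per chromosome.
    """
    if n_markers < 1:
        raise ValueError(f"n_markers must be >= 1, got {n_markers}")
    if n_markers > build.total_length:
        raise ValueError("n_markers exceeds total addressable positions")
    rng = np.random.default_rng(seed)

    # largest-remainder proportional allocation, capped by chromosome size
    lengths = np.array([c.length for c in build], dtype=float)
    ideal = n_markers * lengths / lengths.sum()
    counts = np.floor(ideal).astype(int)
    remainder = n_markers - counts.sum()
    order = np.argsort(-(ideal - counts))
    counts[order[:remainder]] += 1

    chunks = []
    for chrom, k in zip(build, counts):
        if k == 0:
            continue
        pos = np.unique(rng.integers(0, chrom.length, size=k))
        while len(pos) < k:  # redraw on collision
            extra = rng.integers(0, chrom.length, size=k - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        pos.sort()
        chunks.append(
            pd.DataFrame({"chrom": chrom.name, "pos": pos, "gc": _gc_landscape(pos, rng)})
        )
    frame = pd.concat(chunks, ignore_index=True)
    return MarkerMap(platform_name=platform_name, frame=frame)


def split_at_centromere(
    segment: tuple[str, int, int], build: GenomeBuild
) -> list[tuple[int, int, str]]:
    """Split a ``(chrom, start, end)`` interval at the centromere.

    Returns the p-arm and/or q-arm portions as ``(start, end, arm)`` triples,
    ordered and non-overlapping; any portion inside the centromere is
    discarded.  The union of the returned intervals plus the centromere
    overlap exactly reconstructs the input interval.
    """
    chrom, start, end = segment
    c = build[chrom]
    if not (0 <= start < end <= c.length):
        raise ValueError(
            f"segment [{start}, {end}) outside chromosome bounds [0, {c.length})"
        )
    parts: list[tuple[int, int, str]] = []
    if start < c.cen_start:
        parts.append((start, min(end, c.cen_start), "p"))
    if end > c.cen_end:
        parts.append((max(start, c.cen_end), end, "q"))
    return parts
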