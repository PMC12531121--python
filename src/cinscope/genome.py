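"""Genome layouts, fixed-width genomic bins, and per-bin annotation tracks.

The whole package works on a binned representation of a genome: each
chromosome is tiled with fixed-width, half-open bins (the last bin of a
chromosome may be shorter).  Copy-number signal, GC content, mappability
and blacklist status are all stored per bin, aligned 1:1 with a
:class:`GenomeLayout`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "BinTrack",
    "make_genome",
    "toy_genome",
    "GRCH38_AUTOSOME_LENGTHS",
]

# GRCh38 autosome lengths in bp, used (scaled down) for desk-size genomes.
GRCH38_AUTOSOME_LENGTHS: dict[str, int] = {
    "chr1": 248_956_422, "chr2": 242_193_529, "chr3": 198_295_559,
    "chr4": 190_214_555, "chr5": 181_538_259, "chr6": 170_805_979,
    "chr7": 159_345_973, "chr8": 145_138_636, "chr9": 138_394_717,
    "chr10": 133_797_422, "chr11": 135_086_622, "chr12": 133_275_309,
    "chr13": 114_364_328, "chr14": 107_043_718, "chr15": 101_991_189,
    "chr16": 90_338_345, "chr17": 83_257_441, "chr18": 80_373_285,
    "chr19": 58_617_616, "chr20": 64_444_167, "chr21": 46_709_983,
    "chr22": 50_818_468,
}


@dataclass(frozen=True)
class GenomeLayout:
    """An ordered set of chromosomes tiled with fixed-width half-open bins.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, length_bp)`` pairs.
    bin_size:
        Nominal bin width in bp.  Every bin spans exactly ``bin_size`` bp
        except possibly the last bin of each chromosome, which covers the
        remainder.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int
    # Derived, filled in __post_init__ (arrays aligned with bins).
    bin_chrom: np.ndarray = field(repr=False, compare=False, default=None)
    bin_start: np.ndarray = field(repr=False, compare=False, default=None)
    bin_end: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        chroms, starts, ends = [], [], []
        seen: set[str] = set()
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            if name in seen:
                raise ValueError(f"duplicate chromosome name {name!r}")
            seen.add(name)
            edges = np.arange(0, length, self.bin_size, dtype=np.int64)
            chroms.extend([name] * len(edges))
            starts.append(edges)
            ends.append(np.minimum(edges + self.bin_size, length))
        object.__setattr__(self, "bin_chrom", np.asarray(chroms, dtype=object))
        object.__setattr__(self, "bin_start", np.concatenate(starts))
        object.__setattr__(self, "bin_end", np.concatenate(ends))

    # -- basic geometry -------------------------------------------------
    @property
    def n_bins(self) -> int:
        return len(self.bin_start)

    @property
    def bin_widths(self) -> np.ndarray:
        return self.bin_end - self.bin_start

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def chrom_slices(self) -> dict[str, slice]:
        """Mapping of chromosome name -> slice of its bins in genome order."""
        out: dict[str, slice] = {}
        lo = 0
        for name, length in self.chromosomes:
            n = -(-length // self.bin_size)  # ceil division
            out[name] = slice(lo, lo + n)
            lo += n
        return out

    def bins_frame(self) -> pd.DataFrame:
        """Bins as a BED-like DataFrame (chrom, start, end), 0-based half-open."""
        return pd.DataFrame(
            {"chrom": self.bin_chrom, "start": self.bin_start, "end": self.bin_end}
        )

    def __eq__(self, other: object) -> bool:  # dataclass eq chokes on arrays
        if not isinstance(other, GenomeLayout):
            return NotImplemented
        return self.chromosomes == other.chromosomes and self.bin_size == other.bin_size

    def __hash__(self) -> int:
        return hash((self.chromosomes, self.bin_size))


def make_genome(
    chrom_lengths, bin_size: int = 500_000, names: list[str] | None = None
) -> GenomeLayout:
    """Build a :class:`GenomeLayout` from chromosome lengths.

    Parameters
    ----------
    chrom_lengths:
        Iterable of chromosome lengths in bp, or a ``{name: length}`` mapping.
    bin_size:
        Bin width in bp (default 500 kb).
    names:
        Optional chromosome names; defaults to ``chr1..chrN``.
    """
    if isinstance(chrom_lengths, dict):
        names = list(chrom_lengths.keys())
        lengths = list(chrom_lengths.values())
    else:
        lengths = list(chrom_lengths)
        if names is None:
            names = [f"chr{i + 1}" for i in range(len(lengths))]
    if len(names) != len(lengths):
        raise ValueError("names and chrom_lengths disagree in length")
    return GenomeLayout(tuple(zip(names, (int(x) for x in lengths))), int(bin_size))


def toy_genome(scale: int = 5, bin_size: int = 500_000) -> GenomeLayout:
    """A 22-autosome genome with every chromosome shrunk by ``scale``.

    Keeps the multi-chromosome structure of a human genome at desk size;
    ``scale=5`` gives ~1,150 bins of 500 kb with 19-100 bins per
    chromosome, preserving a realistic ratio of event size to chromosome
    size.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    lengths = {name: length // scale for name, length in GRCH38_AUTOSOME_LENGTHS.items()}
    return make_genome(lengths, bin_size=bin_size)


@dataclass
class BinTrack:
    """Per-bin annotation aligned with a :class:`GenomeLayout`.

    Attributes
    ----------
    gc:
        GC fraction per bin in [0, 1]; may be NaN on blacklisted bins.
    mappability:
        Alignability fraction per bin in [0, 1].
    blacklisted:
        Bins excluded from all fitting and statistics.
    """

    gc: np.ndarray
    mappability: np.ndarray
    blacklisted: np.ndarray

    def __post_init__(self) -> None:
        self.gc = np.asarray(self.gc, dtype=float)
        self.mappability = np.asarray(self.mappability, dtype=float)
        self.blacklisted = np.asarray(self.blacklisted, dtype=bool)
        n = len(self.gc)
        if len(self.mappability) != n or len(self.blacklisted) != n:
            raise ValueError("BinTrack arrays must have equal length")
        usable = ~self.blacklisted
        if np.any(~np.isfinite(self.gc[usable])):
            raise ValueError("gc must be defined on all non-blacklisted bins")
        if np.any((self.gc[usable] < 0) | (self.gc[usable] > 1)):
            raise ValueError("gc fractions must lie in [0, 1]")
        if np.any((self.mappability < 0) | (self.mappability > 1)):
            raise ValueError("mappability must lie in [0, 1]")

    @property
    def n_bins(self) -> int:
        return len(self.gc)

    @classmethod
    def uniform(cls, n_bins: int, gc: float = 0.45, mappability: float = 1.0) -> "BinTrack":
        """A featureless track: constant GC, full mappability, no blacklist."""
        return cls(
            gc=np.full(n_bins, gc),
            mappability=np.full(n_bins, mappability),
            blacklisted=np.zeros(n_bins, dtype=bool),
        )

    def to_frame(self, layout: GenomeLayout) -> pd.DataFrame:
        df = layout.bins_frame()
        df["gc"] = self.gc
        df["mappability"] = self.mappability
        df["blacklisted"] = self.blacklisted.astype(int)
        return df
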