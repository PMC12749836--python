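"""Binned genome coordinate system, chromosome classes and positional annotations.

The analysis operates at a fixed bin resolution (100 kb by default in the
pipeline): each chromosome is tiled left-to-right with fixed-width bins,
the last bin of a chromosome may be shorter. Coordinates are 0-based
half-open (BED convention) throughout; bin indices are genome-wide
ordinals following the chromosome order of the chrom.sizes input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Mouse chromosomes carrying rRNA gene clusters.
DEFAULT_RDNA_CHROMS = frozenset({"12", "16", "18", "19"})

_CLASS_RDNA = "rDNA"
_CLASS_NON_RDNA = "non_rDNA"
_CLASS_X = "X"
_CLASS_Y = "Y"

CHROMOSOME_CLASSES = (_CLASS_RDNA, _CLASS_NON_RDNA, _CLASS_X, _CLASS_Y)


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


class ConfigurationError(ValueError):
    """Raised when a configuration is structurally unusable."""


@dataclass(frozen=True)
class GenomeBins:
    """Fixed-width tiling of a genome.

    Attributes
    ----------
    chrom_sizes:
        Ordered mapping chromosome -> length in bp. The iteration order of
        this mapping fixes the genome-wide bin order.
    bin_size:
        Nominal bin width in bp; terminal bins may be shorter.
    chroms, starts, ends:
        Per-bin arrays. ``bin_index`` is implicit: the array position.
    """

    chrom_sizes: dict[str, int]
    bin_size: int
    chroms: np.ndarray = field(repr=False)
    starts: np.ndarray = field(repr=False)
    ends: np.ndarray = field(repr=False)
    chrom_offsets: dict[str, tuple[int, int]] = field(repr=False)

    @property
    def n_bins(self) -> int:
        return self.starts.size

    @property
    def widths(self) -> np.ndarray:
        """Per-bin width in bp (terminal bins may be < bin_size)."""
        return self.ends - self.starts

    @property
    def genome_bp(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_sizes)

    def chrom_slice(self, chrom: str) -> slice:
        """Genome-wide index slice covering one chromosome."""
        start, n = self.chrom_offsets[chrom]
        return slice(start, start + n)

    def bins_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Genome-wide indices of bins overlapping [start, end) by >= 1 bp."""
        if chrom not in self.chrom_offsets:
            raise KeyError(chrom)
        if end <= start:
            return np.empty(0, dtype=np.int64)
        offset, n = self.chrom_offsets[chrom]
        first = start // self.bin_size
        last = (end - 1) // self.bin_size
        first = max(first, 0)
        last = min(last, n - 1)
        if last < first:
            return np.empty(0, dtype=np.int64)
        return np.arange(offset + first, offset + last + 1, dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "bin_index": np.arange(self.n_bins),
            }
        )

    def to_bed(self, path) -> None:
        """Export the bin tiling as BED3."""
        self.to_frame()[["chrom", "start", "end"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column whitespace-separated chrom.sizes file.

    The file order is preserved and becomes the genome-wide chromosome
    order; duplicate names are rejected.
    """
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: expected two columns, got {line!r}")
            name, length = parts[0], parts[1]
            if name in sizes:
                raise ValidationError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = int(length)
    if not sizes:
        raise ConfigurationError(f"{path}: no chromosomes found")
    return sizes


def build_bins(chrom_sizes: dict[str, int], bin_size: int) -> GenomeBins:
    """Tile each chromosome with fixed-width bins.

    Bins cover each chromosome without gaps or overlaps; the last bin of a
    chromosome is truncated at the chromosome end. The total bin count is
    the sum over chromosomes of ceil(length / bin_size).
    """
    if not chrom_sizes:
        raise ConfigurationError("chrom_sizes is empty")
    if bin_size <= 0:
        raise ValidationError(f"bin_size must be positive, got {bin_size}")
    for name, length in chrom_sizes.items():
        if length <= 0:
            raise ValidationError(f"chromosome {name!r} has non-positive length {length}")

    chrom_arrays, start_arrays, end_arrays = [], [], []
    offsets: dict[str, tuple[int, int]] = {}
    cursor = 0
    for name, length in chrom_sizes.items():
        n = -(-length // bin_size)  # ceil division
        starts = np.arange(n, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, length)
        chrom_arrays.append(np.full(n, name, dtype=object))
        start_arrays.append(starts)
        end_arrays.append(ends)
        offsets[name] = (cursor, n)
        cursor += n

    return GenomeBins(
        chrom_sizes=dict(chrom_sizes),
        bin_size=int(bin_size),
        chroms=np.concatenate(chrom_arrays),
        starts=np.concatenate(start_arrays),
        ends=np.concatenate(end_arrays),
        chrom_offsets=offsets,
    )


@dataclass(frozen=True)
class ChromosomeAnnotation:
    """Per-chromosome class and per-bin quintile annotation.

    Classes: ``rDNA`` (chromosomes bearing rRNA gene clusters), ``X``,
    ``Y``, and ``non_rDNA`` for all remaining chromosomes. Quintiles
    partition each chromosome's bins into five nearly equal, ordered
    groups; quintile 1 is the 5'-most fifth (centromere-proximal in the
    acrocentric mouse karyotype).
    """

    chrom_class: dict[str, str]
    bin_class: np.ndarray = field(repr=False)
    bin_quintile: np.ndarray = field(repr=False)

    def class_mask(self, cls: str) -> np.ndarray:
        return self.bin_class == cls


def _quintiles(n: int) -> np.ndarray:
    """Quintile label (1..5) per position for n ordered items.

    Group sizes differ by at most one, larger groups first, so the split
    is contiguous and order-preserving.
    """
    labels = np.empty(n, dtype=np.int8)
    cursor = 0
    for q in range(5):
        size = n // 5 + (1 if q < n % 5 else 0)
        labels[cursor : cursor + size] = q + 1
        cursor += size
    return labels


def annotate(
    bins: GenomeBins,
    rdna_chroms=DEFAULT_RDNA_CHROMS,
    x_name: str = "X",
    y_name: str = "Y",
) -> ChromosomeAnnotation:
    """Assign a chromosome class and a positional quintile to every bin."""
    rdna_chroms = set(rdna_chroms)
    unknown = rdna_chroms - set(bins.chrom_sizes)
    if unknown:
        raise ValidationError(f"rDNA chromosomes not in genome: {sorted(unknown)}")

    chrom_class: dict[str, str] = {}
    for name in bins.chrom_sizes:
        if name in rdna_chroms:
            chrom_class[name] = _CLASS_RDNA
        elif name == x_name:
            chrom_class[name] = _CLASS_X
        elif name == y_name:
            chrom_class[name] = _CLASS_Y
        else:
            chrom_class[name] = _CLASS_NON_RDNA

    bin_class = np.empty(bins.n_bins, dtype=object)
    bin_quintile = np.empty(bins.n_bins, dtype=np.int8)
    for name in bins.chrom_sizes:
        sl = bins.chrom_slice(name)
        bin_class[sl] = chrom_class[name]
        bin_quintile[sl] = _quintiles(sl.stop - sl.start)

    return ChromosomeAnnotation(
        chrom_class=chrom_class, bin_class=bin_class, bin_quintile=bin_quintile
    )
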