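"""Binary contact matrices: assembly from per-cell call files and serialization.

Each microdissected nucleolus contributes one column of a bins x cells
binary matrix: 1 if any called interval of that cell overlaps the bin by
at least 1 bp. The matrix serializes to a TSV (bin_index rows, cell
columns) plus a JSON sidecar carrying bin_size, chromosome order and
optional cell metadata, so the container stays diff-able and
language-neutral.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from nadscope.genome import GenomeBins, ValidationError, build_bins

logger = logging.getLogger(__name__)

ALLELE_LABELS = ("maternal", "paternal", "unassigned")


@dataclass
class ContactMatrix:
    """bins x cells binary contact states.

    ``states`` is a (n_bins, n_cells) uint8 array with entries in {0, 1};
    column order follows ``cells``. ``conditions`` and ``alleles`` are
    optional per-cell labels carried through serialization.
    """

    bins: GenomeBins
    cells: list[str]
    states: np.ndarray
    conditions: list[str] | None = None
    alleles: list[str] | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.ndim != 2:
            raise ValidationError("states must be 2-D (bins x cells)")
        if self.states.shape != (self.bins.n_bins, len(self.cells)):
            raise ValidationError(
                f"states shape {self.states.shape} does not match "
                f"({self.bins.n_bins} bins, {len(self.cells)} cells)"
            )
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("cell identifiers must be unique")
        bad = (self.states > 1).any()
        if bad:
            raise ValidationError("states must be binary")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def column(self, cell: str) -> np.ndarray:
        return self.states[:, self.cells.index(cell)]

    def cell_bin_counts(self) -> np.ndarray:
        """Contacted-bin count per cell (column sums)."""
        return self.states.sum(axis=0).astype(np.int64)

    def subset_cells(self, indices) -> "ContactMatrix":
        indices = list(indices)
        return ContactMatrix(
            bins=self.bins,
            cells=[self.cells[i] for i in indices],
            states=self.states[:, indices],
            conditions=[self.conditions[i] for i in indices] if self.conditions else None,
            alleles=[self.alleles[i] for i in indices] if self.alleles else None,
        )


def _parse_bed_intervals(path, bins: GenomeBins, strict: bool) -> pd.DataFrame:
    """Read BED3+ (strand and extra columns ignored) and validate coordinates."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    known = df["chrom"].isin(bins.chrom_sizes)
    if not known.all():
        unknown = sorted(df.loc[~known, "chrom"].unique())
        if strict:
            raise ValidationError(f"{path}: unknown chromosomes {unknown}")
        logger.warning("%s: skipping %d intervals on unknown chromosomes %s",
                       path, int((~known).sum()), unknown)
        df = df[known]
    for row in df.itertuples():
        limit = bins.chrom_sizes[row.chrom]
        if row.start < 0 or row.end > limit or row.end <= row.start:
            raise ValidationError(
                f"{path}: interval {row.chrom}:{row.start}-{row.end} "
                f"outside chromosome bounds [0, {limit})"
            )
    return df


def read_cell_calls(
    bed_paths,
    bins: GenomeBins,
    cells: list[str] | None = None,
    strict: bool = False,
) -> ContactMatrix:
    """Assemble a contact matrix from per-cell NAD call BED files.

    A bin is marked contacted iff any interval of the cell's file overlaps
    it by >= 1 bp. One column per file, file order preserved. Cell names
    default to file stems.
    """
    bed_paths = [Path(p) for p in bed_paths]
    if cells is None:
        cells = [p.stem for p in bed_paths]
        if len(set(cells)) != len(cells):
            cells = [f"{p.stem}_{i}" for i, p in enumerate(bed_paths)]
    states = np.zeros((bins.n_bins, len(bed_paths)), dtype=np.uint8)
    for j, path in enumerate(bed_paths):
        intervals = _parse_bed_intervals(path, bins, strict)
        for row in intervals.itertuples():
            idx = bins.bins_overlapping(row.chrom, int(row.start), int(row.end))
            states[idx, j] = 1
    return ContactMatrix(bins=bins, cells=list(cells), states=states)


def write_matrix(matrix: ContactMatrix, prefix) -> tuple[Path, Path]:
    """Write the TSV + JSON sidecar container; returns (tsv_path, json_path)."""
    prefix = Path(prefix)
    tsv_path = prefix.with_suffix(".tsv")
    json_path = prefix.with_suffix(".json")
    df = pd.DataFrame(matrix.states, columns=matrix.cells)
    df.insert(0, "bin_index", np.arange(matrix.bins.n_bins))
    df.to_csv(tsv_path, sep="\t", index=False)
    meta = {
        "bin_size": matrix.bins.bin_size,
        "chrom_sizes": matrix.bins.chrom_sizes,
        "cells": matrix.cells,
        "conditions": matrix.conditions,
        "alleles": matrix.alleles,
    }
    json_path.write_text(json.dumps(meta, indent=2))
    return tsv_path, json_path


def read_matrix(prefix) -> ContactMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    bins = build_bins(meta["chrom_sizes"], meta["bin_size"])
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    states = df[meta["cells"]].to_numpy(dtype=np.uint8)
    return ContactMatrix(
        bins=bins,
        cells=list(meta["cells"]),
        states=states,
        conditions=meta.get("conditions"),
        alleles=meta.get("alleles"),
    )


def contacted_intervals(column: np.ndarray, bins: GenomeBins) -> pd.DataFrame:
    """Merge a binary bin column into maximal contacted intervals per chromosome."""
    records = []
    for chrom in bins.chrom_sizes:
        sl = bins.chrom_slice(chrom)
        flags = np.asarray(column[sl], dtype=bool)
        if not flags.any():
            continue
        # run-length boundaries of True runs
        padded = np.concatenate(([False], flags, [False]))
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.nonzero(diff == 1)[0]
        run_ends = np.nonzero(diff == -1)[0]
        starts = bins.starts[sl][run_starts]
        ends = bins.ends[sl][run_ends - 1]
        for s, e in zip(starts, ends):
            records.append((chrom, int(s), int(e)))
    return pd.DataFrame(records, columns=["chrom", "start", "end"])


def write_cell_bed(column: np.ndarray, bins: GenomeBins, path) -> None:
    """Write one cell's contacted bins as a merged-interval BED3 file."""
    contacted_intervals(column, bins).to_csv(path, sep="\t", header=False, index=False)


def write_cf_track(cf_values: np.ndarray, bins: GenomeBins, path, merge: bool = False) -> None:
    """Write a per-bin value vector as bedGraph.

    With ``merge=True`` adjacent equal-valued bins collapse into one record.
    """
    df = pd.DataFrame(
        {"chrom": bins.chroms, "start": bins.starts, "end": bins.ends,
         "value": np.asarray(cf_values, dtype=float)}
    )
    if merge:
        new_block = (df["chrom"].ne(df["chrom"].shift())
                     | df["value"].ne(df["value"].shift())
                     | df["start"].ne(df["end"].shift()))
        block = new_block.cumsum()
        df = df.groupby(block).agg(
            chrom=("chrom", "first"), start=("start", "first"),
            end=("end", "last"), value=("value", "first"),
        )
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6f")


def read_signal_track(path, bins: GenomeBins) -> np.ndarray:
    """Map a bedGraph/TSV signal track onto bins.

    Per-bin value is the coverage-weighted mean of overlapping records;
    bins with no overlapping record are NaN (missing, distinct from zero).
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"], dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return np.full(bins.n_bins, np.nan)
    if not np.issubdtype(df["value"].dtype, np.number):
        bad = df.index[pd.to_numeric(df["value"], errors="coerce").isna()][0]
        raise ValidationError(f"{path}: non-numeric value on line {bad + 1}")
    weighted = np.zeros(bins.n_bins)
    covered = np.zeros(bins.n_bins)
    for row in df.itertuples():
        if row.chrom not in bins.chrom_sizes:
            continue
        idx = bins.bins_overlapping(row.chrom, int(row.start), int(row.end))
        if idx.size == 0:
            continue
        overlap = (np.minimum(bins.ends[idx], row.end)
                   - np.maximum(bins.starts[idx], row.start))
        weighted[idx] += overlap * row.value
        covered[idx] += overlap
    with np.errstate(invalid="ignore", divide="ignore"):
        out = weighted / covered
    out[covered == 0] = np.nan
    return out
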