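"""Condition comparisons and annotation-based NAD classification.

Compares NAD landscapes between two cohorts (e.g. stem cells vs neural
progenitors, untreated vs transcription-inhibited), classifies NAD bins
against lamina-associated-domain (LAD) intervals into NAD-only vs
NAD/LAD types, joins gene tables to CF profiles, and summarizes
expression shifts of gene sets between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from nadscope.cf import CFProfile, NADCallSet
from nadscope.genome import ChromosomeAnnotation, GenomeBins, ValidationError

logger = logging.getLogger(__name__)

NAD_ONLY = "NAD_only"
NAD_LAD = "NAD_LAD"


@dataclass(frozen=True)
class ConditionComparison:
    """Overlap structure of two NAD call sets on the same bins."""

    n_a: int
    n_b: int
    n_common: int
    n_a_specific: int
    n_b_specific: int
    bp_common: int
    bp_a_specific: int
    bp_b_specific: int
    share_of_b_in_a: float
    share_of_a_in_b: float
    class_coverage_delta: pd.Series | None = None


def condition_specific_nads(
    cf_a: CFProfile, cf_b: CFProfile, hi: float = 0.25, lo: float = 0.10
) -> np.ndarray:
    """Bins with CF strictly above ``hi`` in condition A and strictly below
    ``lo`` in condition B (boolean mask)."""
    if hi <= lo:
        raise ValidationError(f"hi must exceed lo, got hi={hi}, lo={lo}")
    if cf_a.bins.n_bins != cf_b.bins.n_bins:
        raise ValidationError("CF profiles are on different bin sets")
    return (cf_a.cf > hi) & (cf_b.cf < lo)


def overlap_report(
    callset_a: NADCallSet,
    callset_b: NADCallSet,
    annotation: ChromosomeAnnotation | None = None,
) -> ConditionComparison:
    """Shared/exclusive NAD bins and bp between two call sets."""
    if callset_a.bins.n_bins != callset_b.bins.n_bins:
        raise ValidationError("call sets are on different bin sets")
    a, b = callset_a.flags, callset_b.flags
    w = callset_a.bins.widths
    common = a & b
    a_only = a & ~b
    b_only = b & ~a
    delta = None
    if annotation is not None:
        delta = (callset_a.coverage_per_class(annotation)
                 - callset_b.coverage_per_class(annotation)).rename("coverage_delta")
    return ConditionComparison(
        n_a=int(a.sum()),
        n_b=int(b.sum()),
        n_common=int(common.sum()),
        n_a_specific=int(a_only.sum()),
        n_b_specific=int(b_only.sum()),
        bp_common=int(w[common].sum()),
        bp_a_specific=int(w[a_only].sum()),
        bp_b_specific=int(w[b_only].sum()),
        share_of_b_in_a=float(common.sum() / b.sum()) if b.any() else np.nan,
        share_of_a_in_b=float(common.sum() / a.sum()) if a.any() else np.nan,
        class_coverage_delta=delta,
    )


def _intervals_to_mask(intervals: pd.DataFrame, bins: GenomeBins) -> np.ndarray:
    mask = np.zeros(bins.n_bins, dtype=bool)
    for row in intervals.itertuples():
        if row.chrom not in bins.chrom_sizes:
            continue
        mask[bins.bins_overlapping(row.chrom, int(row.start), int(row.end))] = True
    return mask


def read_bed_intervals(path) -> pd.DataFrame:
    """Read a BED3+ interval file (extra columns ignored)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"],
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    if df["start"].isna().any() or not np.issubdtype(df["end"].dtype, np.number):
        raise ValidationError(f"{path}: malformed BED intervals")
    return df


def classify_nad_type(callset: NADCallSet, lad_intervals: pd.DataFrame) -> pd.Series:
    """Type each NAD bin: NAD/LAD when it overlaps any LAD interval by
    >= 1 bp, NAD-only otherwise. Non-NAD bins are left unlabelled (NaN)."""
    lad_mask = _intervals_to_mask(lad_intervals, callset.bins)
    types = pd.Series(np.nan, index=np.arange(callset.bins.n_bins), dtype=object)
    types[callset.flags & lad_mask] = NAD_LAD
    types[callset.flags & ~lad_mask] = NAD_ONLY
    return types


def gene_nad_join(
    genes: pd.DataFrame,
    cf: CFProfile,
    callset: NADCallSet | None = None,
    aggregate: str = "max",
) -> pd.DataFrame:
    """Attach a CF and NAD membership to each gene.

    ``genes`` needs columns (gene_id, chrom, start, end); extra columns
    (expression, category) pass through. A gene's CF is the maximum
    (default) or mean CF over the bins it overlaps; the NAD flag is true
    when any overlapped bin is a cohort NAD.
    """
    if aggregate not in ("max", "mean"):
        raise ValidationError(f"aggregate must be 'max' or 'mean', got {aggregate!r}")
    bins = cf.bins
    values = cf.cf
    out = genes.copy()
    gene_cf = np.full(len(genes), np.nan)
    gene_nad = np.zeros(len(genes), dtype=bool)
    for i, row in enumerate(genes.itertuples()):
        if row.chrom not in bins.chrom_sizes:
            continue
        if row.end > bins.chrom_sizes[row.chrom] or row.start < 0:
            raise ValidationError(
                f"gene {row.gene_id}: {row.chrom}:{row.start}-{row.end} beyond chromosome end"
            )
        idx = bins.bins_overlapping(row.chrom, int(row.start), int(row.end))
        if idx.size == 0:
            continue
        gene_cf[i] = values[idx].max() if aggregate == "max" else values[idx].mean()
        if callset is not None:
            gene_nad[i] = bool(callset.flags[idx].any())
    out["cf"] = gene_cf
    if callset is not None:
        out["nad"] = gene_nad
    return out


def gene_density_vs_cf(
    joined: pd.DataFrame, category_col: str = "category", n_strata: int = 10
) -> pd.DataFrame:
    """Per-category gene counts across CF strata (density-vs-CF table)."""
    edges = np.linspace(0.0, 1.0, n_strata + 1)
    rows = []
    for cat, grp in joined.groupby(category_col):
        cf = grp["cf"].to_numpy()
        for i in range(n_strata):
            lo, hi = edges[i], edges[i + 1]
            inside = (cf > lo) & (cf <= hi) if i > 0 else (cf >= lo) & (cf <= hi)
            rows.append({"category": cat, "cf_low": lo, "cf_high": hi,
                         "n_genes": int(inside.sum()),
                         "density": inside.sum() / len(grp)})
    return pd.DataFrame(rows)


def expression_shift_report(
    gene_sets: dict[str, pd.Index | np.ndarray],
    expr_a: pd.Series,
    expr_b: pd.Series,
    low_expr_cutoff: float = 0.1,
    lfc_threshold: float = 1.0,
    sig_flags: pd.Series | None = None,
) -> pd.DataFrame:
    """Up/down counts and low-expression shares of gene sets between conditions.

    A gene is up (down) when log2(B/A) >= lfc_threshold (<= -lfc_threshold)
    and, if ``sig_flags`` is given, flagged significant. Genes missing an
    expression value in either condition are skipped with a warning.
    ``low_expr_share`` is the fraction of the set below ``low_expr_cutoff``
    (RPKM) in condition A.
    """
    rows = []
    for name, members in gene_sets.items():
        members = pd.Index(members)
        present = members[members.isin(expr_a.index) & members.isin(expr_b.index)]
        missing = len(members) - len(present)
        if missing:
            logger.warning("gene set %s: skipping %d genes without expression", name, missing)
        if len(present) == 0:
            rows.append({"set": name, "n": 0, "n_up": 0, "n_down": 0,
                         "low_expr_share": np.nan, "median_abs_lfc": np.nan})
            continue
        a = expr_a.loc[present].astype(float)
        b = expr_b.loc[present].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.log2(b.to_numpy() / a.to_numpy())
        up = lfc >= lfc_threshold
        down = lfc <= -lfc_threshold
        if sig_flags is not None:
            sig = sig_flags.reindex(present).fillna(False).to_numpy(dtype=bool)
            up &= sig
            down &= sig
        rows.append(
            {
                "set": name,
                "n": int(len(present)),
                "n_up": int(np.nansum(up)),
                "n_down": int(np.nansum(down)),
                "low_expr_share": float((a < low_expr_cutoff).mean()),
                "median_abs_lfc": float(np.nanmedian(np.abs(lfc[np.isfinite(lfc)])))
                if np.isfinite(lfc).any() else np.nan,
            }
        )
    return pd.DataFrame(rows)
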