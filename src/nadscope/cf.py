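"""Contact frequencies, NAD calling, coverage statistics and the binomial
false-positive model.

The nucleolar contact frequency (CF) of a bin is the proportion of
microdissected nucleoli whose calls contain that bin. Cohort NADs are
bins with CF strictly above a threshold (default 0.20). Because each
cell also captures a fraction of non-NAD sequence (debris above/below
the nucleolus), a non-NAD bin can recur across cells by chance; the
number of cells n, the per-cell capture probability p of a given
non-NAD bin, and the CF cutoff determine the per-bin false-positive
rate through the binomial tail P(X >= k_min), X ~ Binomial(n, p), with
k_min the smallest count exceeding the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from nadscope.contacts import ContactMatrix
from nadscope.genome import ChromosomeAnnotation, GenomeBins, ValidationError


@dataclass(frozen=True)
class CFProfile:
    """Per-bin contact frequency over a cohort.

    ``counts`` holds the integer number of cells contacting each bin, so
    ``cf = counts / n_cells`` is an exact count proportion.
    """

    bins: GenomeBins
    counts: np.ndarray
    n_cells: int

    @property
    def cf(self) -> np.ndarray:
        return self.counts / self.n_cells


@dataclass(frozen=True)
class NADCallSet:
    """Thresholded NAD calls with merged segments and coverage fractions."""

    bins: GenomeBins
    threshold: float
    flags: np.ndarray
    cf: np.ndarray = field(repr=False)

    @property
    def n_nad_bins(self) -> int:
        return int(self.flags.sum())

    @property
    def nad_bp(self) -> int:
        return int(self.bins.widths[self.flags].sum())

    @property
    def coverage(self) -> float:
        """Genome-wide NAD coverage fraction, bp-weighted."""
        return self.nad_bp / self.bins.genome_bp

    def segments(self) -> pd.DataFrame:
        """Maximal runs of NAD bins merged into intervals."""
        records = []
        for chrom in self.bins.chrom_sizes:
            sl = self.bins.chrom_slice(chrom)
            flags = self.flags[sl]
            if not flags.any():
                continue
            padded = np.concatenate(([False], flags, [False]))
            diff = np.diff(padded.astype(np.int8))
            run_starts = np.nonzero(diff == 1)[0]
            run_ends = np.nonzero(diff == -1)[0]
            for a, b in zip(run_starts, run_ends):
                start = int(self.bins.starts[sl][a])
                end = int(self.bins.ends[sl][b - 1])
                records.append((chrom, start, end, int(b - a), end - start))
        return pd.DataFrame(records, columns=["chrom", "start", "end", "n_bins", "bp"])

    def coverage_per_chromosome(self) -> pd.Series:
        cov = {}
        for chrom in self.bins.chrom_sizes:
            sl = self.bins.chrom_slice(chrom)
            cov[chrom] = float(
                self.bins.widths[sl][self.flags[sl]].sum() / self.bins.chrom_sizes[chrom]
            )
        return pd.Series(cov, name="coverage")

    def coverage_per_class(self, annotation: ChromosomeAnnotation) -> pd.Series:
        cov = {}
        for cls in np.unique(annotation.bin_class):
            mask = annotation.bin_class == cls
            total = self.bins.widths[mask].sum()
            cov[str(cls)] = float(self.bins.widths[mask & self.flags].sum() / total)
        return pd.Series(cov, name="coverage")

    def to_bed(self, path) -> None:
        """Export NAD bins as BED with mean segment CF in the score column."""
        segs = self.segments()
        rows = []
        for seg in segs.itertuples():
            idx = self.bins.bins_overlapping(seg.chrom, seg.start, seg.end)
            rows.append((seg.chrom, seg.start, seg.end, "NAD", float(self.cf[idx].mean())))
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False,
                                  float_format="%.4f")


@dataclass(frozen=True)
class BinomialFPModel:
    """Binomial false-classification model for cohort NAD calling.

    n cells, per-cell capture probability p of a given non-NAD bin, CF
    cutoff ``threshold``. ``k_min`` is the smallest integer count whose
    proportion exceeds the cutoff; ``per_bin_rate`` = P(X >= k_min).
    """

    n: int
    p: float
    threshold: float
    k_min: int
    per_bin_rate: float
    n_bins: int
    expected_false_positives: float

    def report(self) -> dict:
        return {
            "n_cells": self.n,
            "p_noise": self.p,
            "cf_threshold": self.threshold,
            "k_min": self.k_min,
            "per_bin_rate": self.per_bin_rate,
            "n_bins": self.n_bins,
            "expected_false_positives": self.expected_false_positives,
        }


def contact_frequency(matrix: ContactMatrix) -> CFProfile:
    """CF(b) = number of cells contacting bin b / number of cells."""
    if matrix.n_cells < 1:
        raise ValidationError("contact matrix has no cells")
    counts = matrix.states.sum(axis=1).astype(np.int64)
    return CFProfile(bins=matrix.bins, counts=counts, n_cells=matrix.n_cells)


def call_nads(cf: CFProfile, threshold: float = 0.20) -> NADCallSet:
    """Call cohort NADs as bins with CF strictly greater than the threshold."""
    if not 0 <= threshold < 1:
        raise ValidationError(f"threshold must be in [0, 1), got {threshold}")
    values = cf.cf
    flags = values > threshold
    return NADCallSet(bins=cf.bins, threshold=threshold, flags=flags, cf=values)


def binomial_cdf(k: int, n: int, p: float) -> float:
    """P(X <= k) for X ~ Binomial(n, p)."""
    _check_binom_args(k, n, p)
    return float(stats.binom.cdf(k, n, p))


def binomial_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), stable for tails down to ~1e-300."""
    _check_binom_args(k, n, p)
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def _check_binom_args(k: int, n: int, p: float) -> None:
    if not (0 <= k <= n):
        raise ValidationError(f"k must satisfy 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p must be in [0, 1], got {p}")


def min_passing_count(n: int, threshold: float) -> int:
    """Smallest integer k with k/n strictly above the CF threshold."""
    for k in range(n + 1):
        if k / n > threshold:
            return k
    raise ValidationError(f"no count in 0..{n} exceeds threshold {threshold}")


def false_positive_model(
    n: int, p: float, threshold: float = 0.20, n_bins: int | None = None
) -> BinomialFPModel:
    """Expected number of non-NAD bins falsely called NAD at the CF cutoff."""
    if threshold >= 1:
        raise ValidationError("threshold must be < 1")
    k_min = min_passing_count(n, threshold)
    rate = binomial_tail(k_min, n, p)
    n_bins = int(n_bins) if n_bins is not None else 0
    return BinomialFPModel(
        n=n,
        p=p,
        threshold=threshold,
        k_min=k_min,
        per_bin_rate=rate,
        n_bins=n_bins,
        expected_false_positives=n_bins * rate,
    )


def implied_contamination(target_rate: float, n: int, threshold: float = 0.20) -> float:
    """Invert the false-positive model: find p with tail(k_min, n, p) = target_rate.

    The tail is strictly increasing in p, so bisection brackets (0, 1).
    """
    if not (0.0 < target_rate < 1.0):
        raise ValidationError(f"target_rate must be in (0, 1), got {target_rate}")
    k_min = min_passing_count(n, threshold)

    def f(p: float) -> float:
        return binomial_tail(k_min, n, p) - target_rate

    lo, hi = 1e-12, 1.0 - 1e-12
    if f(lo) > 0 or f(hi) < 0:
        raise ValidationError("target_rate not bracketed by p in (0, 1)")
    p_star = brentq(f, lo, hi, xtol=1e-15, rtol=1e-14)
    return float(p_star)


def per_cell_coverage(
    matrix: ContactMatrix, callset: NADCallSet | None = None
) -> pd.DataFrame:
    """Genome-fraction coverage per cell, bp-weighted.

    ``raw`` is contacted bp / genome bp; ``nad_restricted`` (when a cohort
    call set is given) restricts to bins in the cohort NAD set.
    """
    widths = matrix.bins.widths.astype(float)
    genome = matrix.bins.genome_bp
    raw = (widths @ matrix.states) / genome
    out = pd.DataFrame({"cell": matrix.cells, "raw": raw})
    if callset is not None:
        masked = widths * callset.flags
        out["nad_restricted"] = (masked @ matrix.states) / genome
    return out


def per_cell_chrom_coverage(matrix: ContactMatrix, callset: NADCallSet | None = None) -> pd.DataFrame:
    """Per-cell, per-chromosome coverage fractions (cells x chromosomes)."""
    data = {}
    flags = callset.flags if callset is not None else np.ones(matrix.bins.n_bins, bool)
    for chrom in matrix.bins.chrom_sizes:
        sl = matrix.bins.chrom_slice(chrom)
        w = matrix.bins.widths[sl] * flags[sl]
        data[chrom] = (w @ matrix.states[sl]) / matrix.bins.chrom_sizes[chrom]
    return pd.DataFrame(data, index=matrix.cells)


def quintile_coverage_vs_cf(
    matrix: ContactMatrix,
    callset: NADCallSet,
    annotation: ChromosomeAnnotation,
    n_strata: int = 10,
) -> pd.DataFrame:
    """Share of 5'-quintile (quintile-1) sequence among NADs per CF stratum.

    NAD bins with CF > 0 are cut into ``n_strata`` equal-width CF strata;
    within each stratum the bp share falling in quintile 1 is reported.
    """
    flags = callset.flags
    cf = callset.cf
    widths = matrix.bins.widths.astype(float)
    q1 = annotation.bin_quintile == 1
    edges = np.linspace(0.0, 1.0, n_strata + 1)
    rows = []
    for i in range(n_strata):
        lo, hi = edges[i], edges[i + 1]
        in_stratum = flags & (cf > lo) & (cf <= hi)
        total_bp = widths[in_stratum].sum()
        q1_bp = widths[in_stratum & q1].sum()
        rows.append(
            {
                "cf_low": lo,
                "cf_high": hi,
                "n_bins": int(in_stratum.sum()),
                "quintile1_share": q1_bp / total_bp if total_bp > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def class_cf_distribution(cf: CFProfile, annotation: ChromosomeAnnotation) -> pd.DataFrame:
    """Cumulative CF distribution per chromosome class.

    Returns a long table (class, cf, cumulative_fraction) where the
    cumulative fraction at x is P(CF <= x) within the class.
    """
    values = cf.cf
    rows = []
    for cls in np.unique(annotation.bin_class):
        mask = annotation.bin_class == cls
        v = np.sort(values[mask])
        cum = np.arange(1, v.size + 1) / v.size
        for x, c in zip(v, cum):
            rows.append((str(cls), float(x), float(c)))
    return pd.DataFrame(rows, columns=["class", "cf", "cumulative_fraction"])


def rpkm(count: float, total_reads: float, length_bp: float) -> float:
    """Reads per kilobase per million mapped reads: 1e9 * C / (N * L)."""
    if total_reads <= 0:
        raise ValidationError(f"total mapped reads must be positive, got {total_reads}")
    if length_bp <= 0:
        raise ValidationError(f"feature length must be positive, got {length_bp}")
    if count < 0:
        raise ValidationError(f"read count must be non-negative, got {count}")
    return 1e9 * count / (total_reads * length_bp)


def signal_at_nad_classes(
    bin_sets: dict[str, np.ndarray],
    signal: np.ndarray,
    test: str = "welch",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean/median signal per bin set plus pairwise two-sample location tests.

    Missing signal (NaN) is skipped, not treated as zero. Returns
    (per-set summary, pairwise test table with Benjamini-Hochberg adjusted
    p-values). ``test`` is ``welch`` (unequal-variance t) or ``mannwhitney``.
    """
    signal = np.asarray(signal, dtype=float)
    summaries, values = [], {}
    for name, mask in bin_sets.items():
        v = signal[np.asarray(mask, dtype=bool)]
        v = v[~np.isnan(v)]
        if v.size == 0:
            raise ValidationError(f"bin set {name!r} has no non-missing signal")
        values[name] = v
        summaries.append({"set": name, "n": v.size, "mean": v.mean(),
                          "median": float(np.median(v))})
    names = list(values)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = values[names[i]], values[names[j]]
            if test == "welch":
                stat, p = stats.ttest_ind(a, b, equal_var=False)
            elif test == "mannwhitney":
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            else:
                raise ValidationError(f"unknown test {test!r}")
            if not np.isfinite(p) and np.isclose(a.mean(), b.mean()):
                p = 1.0  # zero-variance identical samples: no evidence of difference
            rows.append({"set_a": names[i], "set_b": names[j],
                         "mean_diff": a.mean() - b.mean(),
                         "statistic": float(stat), "p_value": float(p)})
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["p_adj"] = stats.false_discovery_control(tests["p_value"].to_numpy(), method="bh")
    return pd.DataFrame(summaries), tests
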