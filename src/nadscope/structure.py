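"""Cohort robustness and heterogeneity statistics.

Saturation subsampling asks how stable the cohort NAD set is as cells
are added; coverage-matched randomization builds null cohorts with each
cell's contacted-bin count preserved but positions scrambled; Yule's Q
measures cell-cell similarity of binary contact profiles; and the
autocorrelation function (ACF) of per-cell profiles, fitted with
a * exp(-b * lag), summarizes how quickly nucleolar association decays
along the genome (a: initial autocorrelation, b: decay constant per
bin of lag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from nadscope.cf import call_nads, contact_frequency
from nadscope.contacts import ContactMatrix
from nadscope.genome import GenomeBins, ValidationError


@dataclass(frozen=True)
class YuleQResult:
    """Pairwise Yule's Q over cells.

    Q = (ad - bc)/(ad + bc) from the 2x2 concordance counts of two binary
    profiles (a: both contact, b/c: one only, d: neither). Pairs with
    ad + bc = 0 are undefined and stored as NaN.
    """

    cells: list[str]
    q: np.ndarray

    def pair_values(self) -> np.ndarray:
        """Defined Q values of all unordered pairs (diagonal excluded)."""
        iu = np.triu_indices(len(self.cells), k=1)
        vals = self.q[iu]
        return vals[~np.isnan(vals)]


@dataclass(frozen=True)
class ACFCurve:
    """Autocorrelation per lag (1..max_lag), chromosome-combined."""

    lags: np.ndarray
    values: np.ndarray

    def finite(self) -> tuple[np.ndarray, np.ndarray]:
        ok = np.isfinite(self.values)
        return self.lags[ok], self.values[ok]


@dataclass(frozen=True)
class ExpFit:
    """Least-squares fit of a * exp(-b * lag) to an ACF curve."""

    a: float
    b: float
    residual_norm: float
    converged: bool = True

    def predict(self, lags: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-self.b * np.asarray(lags, dtype=float))


def subsample_saturation(
    matrix: ContactMatrix,
    sizes=(20, 30, 40),
    reps: int = 20,
    seed: int = 0,
    threshold: float = 0.20,
) -> pd.DataFrame:
    """NAD-set stability under random subsampling of cells.

    For each subsample size and repetition, the CF profile and NAD set are
    recomputed on the subsample and compared with the full-cohort NAD set
    (Jaccard index of bin sets; coverage ratio in bp).
    """
    for size in sizes:
        if size > matrix.n_cells:
            raise ValidationError(f"subsample size {size} exceeds cohort size {matrix.n_cells}")
    full = call_nads(contact_frequency(matrix), threshold)
    full_set = full.flags
    full_bp = full.nad_bp
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        for rep in range(reps):
            idx = rng.choice(matrix.n_cells, size=size, replace=False)
            sub = call_nads(contact_frequency(matrix.subset_cells(idx)), threshold)
            inter = (sub.flags & full_set).sum()
            union = (sub.flags | full_set).sum()
            rows.append(
                {
                    "size": size,
                    "rep": rep,
                    "jaccard": inter / union if union > 0 else 1.0,
                    "coverage_ratio": sub.nad_bp / full_bp if full_bp > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def randomized_cohort(matrix: ContactMatrix, seed: int = 0) -> ContactMatrix:
    """Coverage-matched randomization.

    Each cell keeps its contacted-bin count, but the contacted bins are
    re-drawn uniformly at random without replacement over the whole
    genome, destroying any positional structure.
    """
    rng = np.random.default_rng(seed)
    n_bins = matrix.bins.n_bins
    states = np.zeros_like(matrix.states)
    for j, count in enumerate(matrix.cell_bin_counts()):
        if count > 0:
            states[rng.choice(n_bins, size=int(count), replace=False), j] = 1
    return ContactMatrix(
        bins=matrix.bins,
        cells=[f"{c}_rand" for c in matrix.cells],
        states=states,
        conditions=matrix.conditions,
        alleles=matrix.alleles,
    )


def yules_q(matrix: ContactMatrix) -> YuleQResult:
    """Pairwise Yule's Q similarity between cells."""
    if matrix.n_cells < 2:
        raise ValidationError("Yule's Q needs at least 2 cells")
    s = matrix.states.astype(np.int64)
    n_bins = matrix.bins.n_bins
    a = s.T @ s
    col = s.sum(axis=0)
    b = col[:, None] - a
    c = col[None, :] - a
    d = n_bins - a - b - c
    num = a * d - b * c
    den = a * d + b * c
    with np.errstate(invalid="ignore", divide="ignore"):
        q = num / den
    q = np.where(den == 0, np.nan, q)
    np.fill_diagonal(q, 1.0)
    return YuleQResult(cells=list(matrix.cells), q=q)


def _profile_acf(profile: np.ndarray, bins: GenomeBins, max_lag: int, weighted: bool) -> ACFCurve:
    """ACF of one per-bin profile, computed within chromosomes and combined.

    Lags never cross chromosome boundaries. For each chromosome the lag-h
    value is the Pearson correlation of (x_1..x_{L-h}) with
    (x_{1+h}..x_L); constant chromosomes are skipped. Chromosome values
    combine by (bins - lag) weights (or a simple mean).
    """
    profile = np.asarray(profile, dtype=float)
    lags = np.arange(1, max_lag + 1)
    values = np.full(max_lag, np.nan)
    per_chrom: list[tuple[np.ndarray, int]] = []
    for chrom in bins.chrom_sizes:
        x = profile[bins.chrom_slice(chrom)]
        if x.size < 2 or np.all(x == x[0]):
            continue
        per_chrom.append((x, x.size))
    if not per_chrom:
        return ACFCurve(lags=lags, values=values)
    for h in lags:
        nums, weights = [], []
        for x, L in per_chrom:
            if L <= h + 1:
                continue
            lead, lag_x = x[:-h], x[h:]
            if lead.std() == 0 or lag_x.std() == 0:
                continue
            r = np.corrcoef(lead, lag_x)[0, 1]
            nums.append(r)
            weights.append(L - h if weighted else 1.0)
        if nums:
            values[h - 1] = np.average(nums, weights=weights)
    return ACFCurve(lags=lags, values=values)


def acf(
    source: ContactMatrix | np.ndarray,
    bins: GenomeBins | None = None,
    max_lag: int = 50,
    weighted: bool = True,
) -> list[ACFCurve] | ACFCurve:
    """ACF per cell of a contact matrix, or of a single per-bin profile."""
    if isinstance(source, ContactMatrix):
        return [
            _profile_acf(source.states[:, j], source.bins, max_lag, weighted)
            for j in range(source.n_cells)
        ]
    if bins is None:
        raise ValidationError("bins required when passing a raw profile")
    return _profile_acf(np.asarray(source), bins, max_lag, weighted)


def fit_exponential(curve: ACFCurve) -> ExpFit:
    """Fit a * exp(-b * x) to the ACF by nonlinear least squares.

    Initialization comes from a log-linear regression on the positive ACF
    values (log ACF = log a - b x); b is constrained non-negative. Raises
    on fewer than 3 finite points; returns ``converged=False`` with the
    initializer if the nonlinear step fails.
    """
    x, y = curve.finite()
    if x.size < 3:
        raise ValidationError(f"exponential fit needs >= 3 finite ACF points, got {x.size}")
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
        a0, b0 = float(np.exp(intercept)), float(max(-slope, 0.0))
    else:
        a0, b0 = max(float(y[0]), 1e-3), 0.1
    try:
        (a, b), _ = optimize.curve_fit(
            lambda t, a, b: a * np.exp(-b * t),
            x.astype(float),
            y.astype(float),
            p0=(a0, b0),
            bounds=((-np.inf, 0.0), (np.inf, np.inf)),
            maxfev=10_000,
        )
        converged = True
    except RuntimeError:
        a, b, converged = a0, b0, False
    resid = y - a * np.exp(-b * x)
    return ExpFit(a=float(a), b=float(b), residual_norm=float(np.linalg.norm(resid)),
                  converged=converged)
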