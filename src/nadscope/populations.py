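"""Subpopulation discovery from per-chromosome NAD coverage.

Cells are featurized by their per-chromosome coverage of cohort NAD
bins and clustered top-down with DIANA (DIvisive ANAlysis): starting
from one cluster, the cluster with the largest diameter is split by
seeding a splinter group with the most dissimilar object and moving
objects whose average dissimilarity favours the splinter, until the
requested number of clusters is reached. Population-specific NADs are
bins with high CF in one population and low CF in the other; their
signal enrichment differences are tested with a pooled bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from nadscope.cf import CFProfile, NADCallSet
from nadscope.contacts import ContactMatrix
from nadscope.genome import ValidationError


@dataclass(frozen=True)
class SplitRecord:
    """One divisive step: a parent cluster split into splinter/remainder."""

    parent: tuple[int, ...]
    splinter: tuple[int, ...]
    remainder: tuple[int, ...]
    diameter: float


@dataclass(frozen=True)
class ClusteringResult:
    """Divisive clustering output: flat labels plus the split history."""

    labels: np.ndarray
    splits: list[SplitRecord] = field(repr=False)
    cells: list[str] | None = None

    @property
    def k(self) -> int:
        return int(np.unique(self.labels).size)

    def to_frame(self) -> pd.DataFrame:
        index = self.cells if self.cells is not None else np.arange(self.labels.size)
        return pd.DataFrame({"cell": index, "cluster": self.labels})


def coverage_matrix(matrix: ContactMatrix, callset: NADCallSet) -> pd.DataFrame:
    """Per-cell per-chromosome coverage of cohort NAD bins (cells x chroms).

    Entry (cell, chrom) = bp of the chromosome's cohort-NAD bins contacted
    by the cell / chromosome length in bp.
    """
    bins = matrix.bins
    data = {}
    for chrom in bins.chrom_sizes:
        sl = bins.chrom_slice(chrom)
        w = bins.widths[sl] * callset.flags[sl]
        data[chrom] = (w @ matrix.states[sl]) / bins.chrom_sizes[chrom]
    return pd.DataFrame(data, index=matrix.cells)


def _split_cluster(members: list[int], dist: np.ndarray) -> tuple[list[int], list[int]]:
    """One DIANA split of ``members`` using the full dissimilarity matrix.

    The splinter group is seeded with the object of maximal average
    dissimilarity to the rest of its cluster; objects then move to the
    splinter while their average dissimilarity to the remainder exceeds
    their average dissimilarity to the splinter (largest positive
    difference first, lowest index breaking ties).
    """
    members = list(members)
    sub = dist[np.ix_(members, members)]
    m = len(members)
    avg_to_rest = sub.sum(axis=1) / (m - 1)
    seed = int(np.argmax(avg_to_rest))  # argmax takes the lowest index on ties
    splinter = [seed]
    remainder = [i for i in range(m) if i != seed]
    while len(remainder) > 1:
        best_gain, best_obj = 0.0, None
        for i in remainder:
            d_rem = sum(sub[i, j] for j in remainder if j != i) / (len(remainder) - 1)
            d_spl = sum(sub[i, j] for j in splinter) / len(splinter)
            gain = d_rem - d_spl
            if gain > best_gain:
                best_gain, best_obj = gain, i
        if best_obj is None:
            break
        splinter.append(best_obj)
        remainder.remove(best_obj)
    return [members[i] for i in sorted(splinter)], [members[i] for i in sorted(remainder)]


def diana(features, k: int, metric: str = "euclidean") -> ClusteringResult:
    """DIvisive ANAlysis clustering down to ``k`` flat clusters.

    ``features`` is an (n_objects, n_features) array or DataFrame (e.g. a
    coverage matrix). At every step the cluster with the largest diameter
    (maximal pairwise dissimilarity) is split. Deterministic: ties break
    toward the lowest object index.
    """
    if isinstance(features, pd.DataFrame):
        cells = list(features.index.astype(str))
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        cells = None
    n = X.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds number of objects {n}")
    if not np.isfinite(X).all():
        raise ValidationError("features must be finite")
    dist = squareform(pdist(X, metric=metric))

    clusters: list[list[int]] = [list(range(n))]
    splits: list[SplitRecord] = []
    while len(clusters) < k:
        diameters = [
            dist[np.ix_(c, c)].max() if len(c) > 1 else 0.0 for c in clusters
        ]
        target = int(np.argmax(diameters))
        if diameters[target] == 0.0:
            # all remaining clusters are singletons or duplicates: split the
            # first splittable cluster into arbitrary halves of identical points
            target = next((i for i, c in enumerate(clusters) if len(c) > 1), None)
            if target is None:
                break
            members = clusters.pop(target)
            splinter, remainder = [members[0]], members[1:]
        else:
            members = clusters.pop(target)
            splinter, remainder = _split_cluster(members, dist)
        splits.append(
            SplitRecord(
                parent=tuple(members),
                splinter=tuple(splinter),
                remainder=tuple(remainder),
                diameter=float(dist[np.ix_(members, members)].max()),
            )
        )
        clusters.append(remainder)
        clusters.append(splinter)

    labels = np.zeros(n, dtype=int)
    # stable label assignment: clusters ordered by smallest member index
    for lab, c in enumerate(sorted(clusters, key=min), start=1):
        labels[c] = lab
    return ClusteringResult(labels=labels, splits=splits, cells=cells)


def population_specific_nads(
    cf_pop1: CFProfile,
    cf_pop2: CFProfile,
    hi: float = 0.30,
    lo: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Bins specific to one population: CF > hi there and CF < lo in the other.

    Returns boolean masks (set1, set2); both inequalities strict, so the
    sets are disjoint whenever hi > lo.
    """
    if hi <= lo:
        raise ValidationError(f"hi must exceed lo, got hi={hi}, lo={lo}")
    if cf_pop1.bins.n_bins != cf_pop2.bins.n_bins:
        raise ValidationError("CF profiles are on different bin sets")
    c1, c2 = cf_pop1.cf, cf_pop2.cf
    set1 = (c1 > hi) & (c2 < lo)
    set2 = (c2 > hi) & (c1 < lo)
    return set1, set2


def bootstrap_enrichment(
    set1: np.ndarray,
    set2: np.ndarray,
    signal: np.ndarray,
    iters: int = 1000,
    seed: int = 0,
    method: str = "bootstrap",
) -> dict:
    """Empirical test of the signal-enrichment difference between two bin sets.

    Observed statistic: mean(signal | set1) - mean(signal | set2) over
    non-missing bins. The null redraws both groups (sizes preserved) from
    the pooled bins — with replacement for ``method="bootstrap"``, or by
    label permutation for ``method="permutation"``. One-sided empirical
    p-value with the +1 correction: p = (#{null >= observed} + 1)/(iters + 1).
    """
    signal = np.asarray(signal, dtype=float)
    idx1 = np.nonzero(np.asarray(set1, dtype=bool))[0]
    idx2 = np.nonzero(np.asarray(set2, dtype=bool))[0]
    idx1 = idx1[~np.isnan(signal[idx1])]
    idx2 = idx2[~np.isnan(signal[idx2])]
    if idx1.size == 0 or idx2.size == 0:
        raise ValidationError("both bin sets must contain non-missing signal")
    observed = signal[idx1].mean() - signal[idx2].mean()
    pooled = np.concatenate([idx1, idx2])
    n1 = idx1.size
    rng = np.random.default_rng(seed)
    null = np.empty(iters)
    for it in range(iters):
        if method == "bootstrap":
            g1 = rng.choice(pooled, size=n1, replace=True)
            g2 = rng.choice(pooled, size=idx2.size, replace=True)
        elif method == "permutation":
            perm = rng.permutation(pooled)
            g1, g2 = perm[:n1], perm[n1:]
        else:
            raise ValidationError(f"unknown method {method!r}")
        null[it] = signal[g1].mean() - signal[g2].mean()
    p = (int((null >= observed).sum()) + 1) / (iters + 1)
    return {
        "observed": float(observed),
        "p_value": float(p),
        "null": null,
        "n1": int(n1),
        "n2": int(idx2.size),
        "method": method,
    }
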