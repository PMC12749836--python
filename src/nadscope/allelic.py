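"""Allele-resolved NAD classification.

In a hybrid genome each bin has two haplotypes whose contacts are
called independently, giving a maternal and a paternal CF per bin. A
bin is a bi-allelic NAD when both allele CFs pass the NAD threshold,
mono-allelic when exactly one does, and unclassified otherwise. A
mono-allelic NAD is parent-specific only under a stringent hi/lo rule
(high CF on one allele AND low CF on the other), distinguishing
"always the same parent" from "either parent, one per cell".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nadscope.cf import CFProfile, contact_frequency
from nadscope.contacts import ContactMatrix
from nadscope.genome import ChromosomeAnnotation, GenomeBins, ValidationError

STATUS_NONE = "none"
STATUS_BIALLELIC = "biallelic"
STATUS_MONO_MATERNAL = "mono_maternal"
STATUS_MONO_PATERNAL = "mono_paternal"


@dataclass(frozen=True)
class AllelicCallSet:
    """Per-bin allele-resolved NAD classification."""

    bins: GenomeBins
    cf_maternal: np.ndarray
    cf_paternal: np.ndarray
    threshold: float
    status: np.ndarray = field(repr=False)

    @property
    def nad_mask(self) -> np.ndarray:
        """Haploid-projected NAD set: bins passing on at least one allele."""
        return self.status != STATUS_NONE

    @property
    def mono_mask(self) -> np.ndarray:
        return (self.status == STATUS_MONO_MATERNAL) | (self.status == STATUS_MONO_PATERNAL)

    @property
    def biallelic_mask(self) -> np.ndarray:
        return self.status == STATUS_BIALLELIC

    @property
    def haploid_coverage(self) -> float:
        """bp fraction of the (haploid) genome in the projected NAD set."""
        return float(self.bins.widths[self.nad_mask].sum() / self.bins.genome_bp)

    @property
    def diploid_coverage(self) -> float:
        """(maternal NAD bp + paternal NAD bp) / (2 x genome bp)."""
        w = self.bins.widths
        mat_bp = w[(self.status == STATUS_BIALLELIC) | (self.status == STATUS_MONO_MATERNAL)].sum()
        pat_bp = w[(self.status == STATUS_BIALLELIC) | (self.status == STATUS_MONO_PATERNAL)].sum()
        return float((mat_bp + pat_bp) / (2 * self.bins.genome_bp))

    @property
    def diploid_mbp(self) -> float:
        return self.diploid_coverage * 2 * self.bins.genome_bp / 1e6

    def mono_fraction(self, per: str = "bin") -> float:
        """Mono-allelic share of NADs, per ``bin`` or per merged ``segment``.

        A segment (maximal run of projected NAD bins) counts as
        bi-allelic if any of its bins is bi-allelic.
        """
        if per == "bin":
            n_nad = int(self.nad_mask.sum())
            return float(self.mono_mask.sum() / n_nad) if n_nad else np.nan
        if per != "segment":
            raise ValidationError(f"per must be 'bin' or 'segment', got {per!r}")
        mono_segments = total = 0
        for chrom in self.bins.chrom_sizes:
            sl = self.bins.chrom_slice(chrom)
            nad = self.nad_mask[sl]
            bi = self.biallelic_mask[sl]
            padded = np.concatenate(([False], nad, [False]))
            diff = np.diff(padded.astype(np.int8))
            for a, b in zip(np.nonzero(diff == 1)[0], np.nonzero(diff == -1)[0]):
                total += 1
                if not bi[a:b].any():
                    mono_segments += 1
        return mono_segments / total if total else np.nan


def allelic_cf(
    matrix_maternal: ContactMatrix, matrix_paternal: ContactMatrix
) -> tuple[CFProfile, CFProfile]:
    """Contact frequency computed independently per allele."""
    if matrix_maternal.cells != matrix_paternal.cells:
        raise ValidationError("maternal and paternal matrices have different cells")
    if matrix_maternal.bins.n_bins != matrix_paternal.bins.n_bins:
        raise ValidationError("maternal and paternal matrices are on different bins")
    return contact_frequency(matrix_maternal), contact_frequency(matrix_paternal)


def classify_allelic(
    cf_maternal: CFProfile, cf_paternal: CFProfile, nad_threshold: float = 0.20
) -> AllelicCallSet:
    """Classify bins as bi-allelic, mono-allelic (either parent) or none.

    The per-allele rule reuses the cohort NAD threshold: an allele
    "passes" when its CF is strictly above ``nad_threshold``.
    """
    if not 0 <= nad_threshold < 1:
        raise ValidationError(f"nad_threshold must be in [0, 1), got {nad_threshold}")
    cm, cp = cf_maternal.cf, cf_paternal.cf
    status = np.full(cm.size, STATUS_NONE, dtype=object)
    mat_pass = cm > nad_threshold
    pat_pass = cp > nad_threshold
    status[mat_pass & pat_pass] = STATUS_BIALLELIC
    status[mat_pass & ~pat_pass] = STATUS_MONO_MATERNAL
    status[~mat_pass & pat_pass] = STATUS_MONO_PATERNAL
    return AllelicCallSet(
        bins=cf_maternal.bins,
        cf_maternal=cm,
        cf_paternal=cp,
        threshold=nad_threshold,
        status=status,
    )


def parent_specific(
    cf_maternal: CFProfile, cf_paternal: CFProfile, hi: float = 0.25, lo: float = 0.10
) -> pd.DataFrame:
    """Stringent parent-specific flags: CF > hi on one allele, < lo on the other."""
    if hi <= lo:
        raise ValidationError(f"hi must exceed lo, got hi={hi}, lo={lo}")
    cm, cp = cf_maternal.cf, cf_paternal.cf
    return pd.DataFrame(
        {
            "maternal_specific": (cm > hi) & (cp < lo),
            "paternal_specific": (cp > hi) & (cm < lo),
        }
    )


def classify_allelic_per_cell(
    matrix_maternal: ContactMatrix, matrix_paternal: ContactMatrix
) -> pd.DataFrame:
    """Per-nucleolus mono/bi-allelic contact proportions.

    Mono- vs bi-allelic contact is a property of a single nucleolus: a
    contacted bin is bi-allelic in a cell when both haplotypes are called
    there, mono-allelic when exactly one is. Aggregating the same bin over
    cells loses this (a bin contacting the maternal allele in one cell and
    the paternal in another has intermediate CF on both alleles), so the
    cohort-CF rule in :func:`classify_allelic` and this per-cell view are
    complementary granularities.
    """
    if matrix_maternal.cells != matrix_paternal.cells:
        raise ValidationError("maternal and paternal matrices have different cells")
    m = matrix_maternal.states.astype(bool)
    p = matrix_paternal.states.astype(bool)
    contacted = (m | p).sum(axis=0)
    biallelic = (m & p).sum(axis=0)
    mono = contacted - biallelic
    with np.errstate(invalid="ignore", divide="ignore"):
        mono_share = np.where(contacted > 0, mono / contacted, np.nan)
    return pd.DataFrame(
        {
            "cell": matrix_maternal.cells,
            "n_contacted": contacted,
            "n_biallelic": biallelic,
            "n_mono": mono,
            "mono_share": mono_share,
        }
    )


def allelic_summaries(
    callset: AllelicCallSet, annotation: ChromosomeAnnotation | None = None
) -> dict:
    """Mono/bi counts (overall and per chromosome class), coverage, CF contrast."""
    out: dict = {
        "n_nad_bins": int(callset.nad_mask.sum()),
        "n_biallelic": int(callset.biallelic_mask.sum()),
        "n_mono_maternal": int((callset.status == STATUS_MONO_MATERNAL).sum()),
        "n_mono_paternal": int((callset.status == STATUS_MONO_PATERNAL).sum()),
        "mono_fraction_bin": callset.mono_fraction("bin"),
        "mono_fraction_segment": callset.mono_fraction("segment"),
        "haploid_coverage": callset.haploid_coverage,
        "diploid_coverage": callset.diploid_coverage,
        "diploid_mbp": callset.diploid_mbp,
    }
    max_cf = np.maximum(callset.cf_maternal, callset.cf_paternal)
    bi, mono = callset.biallelic_mask, callset.mono_mask
    out["mean_max_cf_biallelic"] = float(max_cf[bi].mean()) if bi.any() else np.nan
    out["mean_max_cf_mono"] = float(max_cf[mono].mean()) if mono.any() else np.nan
    if annotation is not None:
        per_class = {}
        for cls in np.unique(annotation.bin_class):
            mask = annotation.bin_class == cls
            n_nad = int((callset.nad_mask & mask).sum())
            n_bi = int((callset.biallelic_mask & mask).sum())
            per_class[str(cls)] = {
                "n_nad_bins": n_nad,
                "n_biallelic": n_bi,
                "biallelic_share": n_bi / n_nad if n_nad else np.nan,
            }
        out["per_class"] = per_class
    return out
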