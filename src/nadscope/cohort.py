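"""Ground-truthed synthetic single-nucleolus cohorts.

The generator emulates the statistical structure of single-nucleolus
capture at bin resolution: contiguous NAD blocks with per-bin contact
probabilities, boosted contacts on rDNA-bearing chromosomes, two (or
more) cell subpopulations with distinct per-chromosome contact weights,
per-cell capture of roughly 15% of the genome of which about one-third
is contamination from non-NAD regions, and (optionally) allele-resolved
contacts that are predominantly mono-allelic with the contacted allele
chosen independently per cell.

The unit of simulation is the binary 100 kb bin call; no read-level
artefacts (amplification bias, alignment) are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nadscope.contacts import ContactMatrix, write_cell_bed
from nadscope.genome import DEFAULT_RDNA_CHROMS, GenomeBins, ValidationError, build_bins

# Default toy genome: 21 "chromosomes" shaped like a scaled-down mouse
# karyotype (autosomes 1..19 decreasing in size, then X and Y), 100 kb bins.
DEFAULT_CHROM_SIZES = {
    **{str(i): (200 - 6 * i) * 100_000 for i in range(1, 20)},
    "X": 170 * 100_000,
    "Y": 20 * 100_000,
}

# Allele regimes for hybrid cohorts.
REGIME_BIALLELIC = 0
REGIME_RANDOM_MONO = 1
REGIME_FIXED_MATERNAL = 2
REGIME_FIXED_PATERNAL = 3


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the capture statistics the method assumes: ~15% of
    the genome recovered per nucleolus with about one-third of captured
    bins arising from non-NAD regions, 86% of allele-resolved NADs
    mono-allelic, and ~1% of mono-allelic NADs fixed to one parent.
    """

    n_cells: int = 53
    bin_size: int = 100_000
    chrom_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    rdna_chroms: tuple[str, ...] = tuple(sorted(DEFAULT_RDNA_CHROMS))
    recovery_fraction: float = 0.15
    contamination_fraction: float = 1.0 / 3.0
    nad_fraction: float = 0.25
    nad_block_length_mean: float = 5.0
    rdna_contact_boost: float = 2.0
    n_populations: int = 2
    population_weights: dict[int, dict[str, float]] | None = None
    population_mix: tuple[float, ...] | None = None
    allele_mode: str = "none"  # {"none", "hybrid"}
    monoallelic_fraction: float = 0.86
    parent_specific_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("recovery_fraction", "contamination_fraction",
                     "monoallelic_fraction", "parent_specific_fraction",
                     "nad_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.nad_block_length_mean < 1:
            raise ValidationError("nad_block_length_mean must be >= 1")
        if self.allele_mode not in ("none", "hybrid"):
            raise ValidationError(f"unknown allele_mode {self.allele_mode!r}")
        if self.n_populations < 1:
            raise ValidationError("n_populations must be >= 1")

    def build_bins(self) -> GenomeBins:
        return build_bins(self.chrom_sizes, self.bin_size)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rdna_chroms"] = list(self.rdna_chroms)
        if self.population_mix is not None:
            d["population_mix"] = list(self.population_mix)
        return d


@dataclass
class CohortTruth:
    """Ground truth of a synthetic cohort.

    ``contact_prob`` has shape (n_bins, 2): columns are the maternal and
    paternal per-allele contact probabilities (identical when
    allele_mode is "none"; probability 0 on non-NAD bins — contamination
    is modelled at capture, not in truth). ``allele_regime`` marks how a
    NAD bin distributes between alleles; ``cell_allele`` records, per
    cell and bin, the allele a random-mono bin contacts in that cell
    (0 = maternal, 1 = paternal).
    """

    bins: GenomeBins
    nad: np.ndarray
    contact_prob: np.ndarray
    population: np.ndarray
    allele_regime: np.ndarray | None = None
    cell_allele: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins


def _default_population_weights(config: SimulationConfig) -> dict[int, dict[str, float]]:
    """Per-population per-chromosome contact weights.

    For two populations the default plants the mutually exclusive
    rDNA-chromosome pattern: the first half of the rDNA chromosomes
    contacts preferentially in population 1, the second half in
    population 2; other chromosomes are unweighted.
    """
    chroms = list(config.chrom_sizes)
    weights = {p: {c: 1.0 for c in chroms} for p in range(1, config.n_populations + 1)}
    if config.n_populations >= 2:
        rdna = [c for c in config.rdna_chroms if c in config.chrom_sizes]
        half = len(rdna) // 2 if len(rdna) >= 2 else len(rdna)
        for c in rdna[:half]:
            weights[1][c] = 2.0
            weights[2][c] = 0.2
        for c in rdna[half:]:
            weights[1][c] = 0.2
            weights[2][c] = 2.0
    return weights


def simulate_truth(config: SimulationConfig) -> CohortTruth:
    """Draw the ground truth: NAD blocks, contact probabilities, populations.

    NAD bins form contiguous blocks with geometric lengths (mean
    ``nad_block_length_mean``); gaps are geometric with mean chosen so the
    expected NAD fraction equals ``nad_fraction``. Each block carries a
    base contact probability drawn uniformly in [0.25, 0.95]; bins on
    rDNA chromosomes are multiplied by ``rdna_contact_boost`` (clipped at
    1). Deterministic given ``config.seed``.
    """
    bins = config.build_bins()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    nad = np.zeros(bins.n_bins, dtype=bool)
    base_prob = np.zeros(bins.n_bins, dtype=float)
    block_mean = config.nad_block_length_mean
    if config.nad_fraction > 0:
        gap_mean = max(block_mean * (1 - config.nad_fraction) / config.nad_fraction, 1.0)
    else:
        gap_mean = np.inf

    for chrom in config.chrom_sizes:
        sl = bins.chrom_slice(chrom)
        n = sl.stop - sl.start
        pos = 0
        # start in a gap or a block proportionally to their expected share
        in_block = rng.random() < config.nad_fraction and config.nad_fraction > 0
        while pos < n:
            if in_block:
                length = rng.geometric(1.0 / block_mean)
                end = min(pos + length, n)
                nad[sl.start + pos : sl.start + end] = True
                base_prob[sl.start + pos : sl.start + end] = rng.uniform(0.25, 0.95)
                pos = end
            else:
                if not np.isfinite(gap_mean):
                    break
                pos += rng.geometric(1.0 / gap_mean)
            in_block = not in_block

    rdna_mask = np.isin(bins.chroms, [c for c in config.rdna_chroms])
    base_prob[nad & rdna_mask] = np.clip(
        base_prob[nad & rdna_mask] * config.rdna_contact_boost, 0.0, 1.0
    )

    mix = config.population_mix or tuple([1.0 / config.n_populations] * config.n_populations)
    population = rng.choice(
        np.arange(1, config.n_populations + 1), size=config.n_cells, p=np.asarray(mix) / sum(mix)
    )

    contact_prob = np.stack([base_prob, base_prob], axis=1)
    allele_regime = None
    cell_allele = None
    if config.allele_mode == "hybrid":
        allele_regime = np.full(bins.n_bins, -1, dtype=np.int8)
        nad_idx = np.nonzero(nad)[0]
        u = rng.random(nad_idx.size)
        mono = u < config.monoallelic_fraction
        allele_regime[nad_idx[~mono]] = REGIME_BIALLELIC
        mono_idx = nad_idx[mono]
        v = rng.random(mono_idx.size)
        fixed = v < config.parent_specific_fraction
        fixed_idx = mono_idx[fixed]
        parent = rng.random(fixed_idx.size) < 0.5
        allele_regime[fixed_idx[parent]] = REGIME_FIXED_MATERNAL
        allele_regime[fixed_idx[~parent]] = REGIME_FIXED_PATERNAL
        allele_regime[mono_idx[~fixed]] = REGIME_RANDOM_MONO
        # per-cell allele choice for random-mono bins (Bernoulli 1/2)
        cell_allele = (rng.random((bins.n_bins, config.n_cells)) < 0.5).astype(np.int8)
        contact_prob = np.stack([base_prob, base_prob], axis=1)
        contact_prob[allele_regime == REGIME_FIXED_MATERNAL, 1] = 0.0
        contact_prob[allele_regime == REGIME_FIXED_PATERNAL, 0] = 0.0

    return CohortTruth(
        bins=bins,
        nad=nad,
        contact_prob=contact_prob,
        population=population,
        allele_regime=allele_regime,
        cell_allele=cell_allele,
    )


def _population_weight_vector(config: SimulationConfig, bins: GenomeBins, pop: int) -> np.ndarray:
    weights = config.population_weights or _default_population_weights(config)
    per_chrom = weights[pop]
    out = np.ones(bins.n_bins)
    for chrom in bins.chrom_sizes:
        out[bins.chrom_slice(chrom)] = per_chrom.get(chrom, 1.0)
    return out


def simulate_capture(
    truth: CohortTruth, config: SimulationConfig
) -> tuple[ContactMatrix, ContactMatrix | None, ContactMatrix | None]:
    """Simulate per-cell capture from the truth.

    For each cell: (1) true contacts are Bernoulli draws per NAD bin at
    its population-weighted contact probability, rescaled so the
    expected true-contact content is (1 - contamination_fraction) x
    recovery_fraction x n_bins — probability-1 contacts are structural
    and never thinned; (2) contamination adds an exact count of
    uniformly chosen non-NAD bins, contamination_fraction x
    recovery_fraction x n_bins per cell. Returns (total, maternal,
    paternal); the allele matrices are None unless allele_mode="hybrid".
    Deterministic given config.seed (one independent RNG stream per cell).
    """
    bins = truth.bins
    n_bins = bins.n_bins
    hybrid = config.allele_mode == "hybrid"
    target_true = (1.0 - config.contamination_fraction) * config.recovery_fraction * n_bins
    n_contam = int(round(config.contamination_fraction * config.recovery_fraction * n_bins))
    non_nad_idx = np.nonzero(~truth.nad)[0]
    if n_contam > non_nad_idx.size:
        raise ValidationError(
            f"requested contamination ({n_contam} bins) exceeds available "
            f"non-NAD bins ({non_nad_idx.size})"
        )

    streams = np.random.SeedSequence(config.seed).spawn(config.n_cells + 1)[1:]
    total = np.zeros((n_bins, config.n_cells), dtype=np.uint8)
    maternal = np.zeros((n_bins, config.n_cells), dtype=np.uint8) if hybrid else None
    paternal = np.zeros((n_bins, config.n_cells), dtype=np.uint8) if hybrid else None

    for j in range(config.n_cells):
        rng = np.random.default_rng(streams[j])
        weight = _population_weight_vector(config, bins, int(truth.population[j]))
        p_mat = np.clip(truth.contact_prob[:, 0] * weight, 0.0, 1.0)
        p_pat = np.clip(truth.contact_prob[:, 1] * weight, 0.0, 1.0)
        # per-bin probability that the bin is contacted on at least one allele
        if hybrid:
            regime = truth.allele_regime
            p_any = np.where(regime == REGIME_BIALLELIC,
                             1.0 - (1.0 - p_mat) * (1.0 - p_pat),
                             np.maximum(p_mat, p_pat))
            p_any = np.where(truth.nad, p_any, 0.0)
        else:
            p_any = np.where(truth.nad, p_mat, 0.0)
        mass = p_any.sum()
        scale = target_true / mass if mass > 0 else 0.0
        p_eff = np.clip(p_any * scale, 0.0, 1.0)
        p_eff[p_any >= 1.0] = 1.0  # structural contacts are never thinned
        draws = rng.random(n_bins) < p_eff
        contacted = draws & truth.nad
        total[contacted, j] = 1

        if hybrid:
            regime = truth.allele_regime
            idx = np.nonzero(contacted)[0]
            for b in idx:
                r = regime[b]
                if r == REGIME_BIALLELIC:
                    maternal[b, j] = 1
                    paternal[b, j] = 1
                elif r == REGIME_FIXED_MATERNAL:
                    maternal[b, j] = 1
                elif r == REGIME_FIXED_PATERNAL:
                    paternal[b, j] = 1
                else:  # random mono: the cell's coin flip decides the allele
                    if truth.cell_allele[b, j] == 0:
                        maternal[b, j] = 1
                    else:
                        paternal[b, j] = 1

        if n_contam > 0:
            contam_bins = rng.choice(non_nad_idx, size=n_contam, replace=False)
            total[contam_bins, j] = 1
            if hybrid:
                side = rng.random(n_contam) < 0.5
                maternal[contam_bins[side], j] = 1
                paternal[contam_bins[~side], j] = 1

    cells = [f"cell_{j:03d}" for j in range(config.n_cells)]
    make = lambda s: ContactMatrix(bins=bins, cells=list(cells), states=s)
    return (
        make(total),
        make(maternal) if hybrid else None,
        make(paternal) if hybrid else None,
    )


def write_cohort(
    matrix: ContactMatrix,
    truth: CohortTruth,
    config: SimulationConfig,
    out_dir,
    maternal: ContactMatrix | None = None,
    paternal: ContactMatrix | None = None,
) -> dict[str, Path]:
    """Write a cohort to disk: one merged-interval BED per cell, truth
    tables as TSV, and the configuration as YAML."""
    out_dir = Path(out_dir)
    calls_dir = out_dir / "calls"
    calls_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for j, cell in enumerate(matrix.cells):
        bed = calls_dir / f"{cell}.bed"
        write_cell_bed(matrix.states[:, j], matrix.bins, bed)
        paths[cell] = bed
        if maternal is not None:
            write_cell_bed(maternal.states[:, j], matrix.bins, calls_dir / f"{cell}.maternal.bed")
            write_cell_bed(paternal.states[:, j], matrix.bins, calls_dir / f"{cell}.paternal.bed")

    truth_df = pd.DataFrame(
        {
            "bin_index": np.arange(truth.n_bins),
            "chrom": truth.bins.chroms,
            "start": truth.bins.starts,
            "end": truth.bins.ends,
            "nad": truth.nad.astype(int),
            "p_maternal": truth.contact_prob[:, 0],
            "p_paternal": truth.contact_prob[:, 1],
        }
    )
    if truth.allele_regime is not None:
        truth_df["allele_regime"] = truth.allele_regime
    truth_df.to_csv(out_dir / "truth_bins.tsv", sep="\t", index=False)
    pd.DataFrame({"cell": matrix.cells, "population": truth.population}).to_csv(
        out_dir / "truth_cells.tsv", sep="\t", index=False
    )
    chrom_sizes_path = out_dir / "chrom.sizes"
    with open(chrom_sizes_path, "w") as fh:
        for name, length in matrix.bins.chrom_sizes.items():
            fh.write(f"{name}\t{length}\n")
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    paths["truth_bins"] = out_dir / "truth_bins.tsv"
    paths["truth_cells"] = out_dir / "truth_cells.tsv"
    paths["config"] = out_dir / "config.yaml"
    paths["chrom_sizes"] = chrom_sizes_path
    return paths


def preset_config(name: str, seed: int = 0, n_cells: int | None = None) -> SimulationConfig:
    """Named cohort presets.

    ``esc``: heterogeneous cohort of 53 cells with two subpopulations.
    ``npc``: 23 cells, fewer NADs, single more homogeneous population.
    ``actd``: 34 cells where non-rDNA contacts are strongly reduced
    (nucleolar-stress scenario; rDNA-chromosome contacts retained).
    ``hybrid``: 50 cells with allele-resolved, predominantly mono-allelic
    contacts.
    """
    if name == "esc":
        cfg = SimulationConfig(n_cells=53, seed=seed)
    elif name == "npc":
        cfg = SimulationConfig(n_cells=23, nad_fraction=0.18, n_populations=1, seed=seed)
    elif name == "actd":
        cfg = SimulationConfig(n_cells=34, recovery_fraction=0.10, n_populations=1, seed=seed)
        weights = {1: {c: 1.0 for c in cfg.chrom_sizes}}
        for c in cfg.chrom_sizes:
            if c not in cfg.rdna_chroms:
                weights[1][c] = 0.3
        cfg.population_weights = weights
    elif name == "hybrid":
        cfg = SimulationConfig(n_cells=50, allele_mode="hybrid", n_populations=1, seed=seed)
    else:
        raise ValidationError(f"unknown preset {name!r}")
    if n_cells is not None:
        cfg.n_cells = n_cells
    return cfg
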