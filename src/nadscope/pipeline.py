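"""End-to-end pipeline orchestration with a JSON run manifest.

The pipeline chains: assemble (or simulate) -> contact frequency ->
NAD calling -> per-cell coverage -> optional cohort-structure,
population and allelic stages. Every random stage draws from a seed
recorded in the manifest; reruns with the same configuration are
bit-identical for deterministic stages.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nadscope import allelic as allelic_mod
from nadscope.cf import (
    call_nads,
    contact_frequency,
    false_positive_model,
    per_cell_coverage,
)
from nadscope.cohort import SimulationConfig, preset_config, simulate_capture, simulate_truth, write_cohort
from nadscope.contacts import read_cell_calls, write_cf_track, write_matrix
from nadscope.genome import ValidationError, annotate, build_bins, read_chrom_sizes, DEFAULT_RDNA_CHROMS
from nadscope.populations import coverage_matrix, diana
from nadscope.structure import acf, fit_exponential, subsample_saturation, yules_q

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a pipeline run (YAML-loadable; flags may override)."""

    out_dir: str = "nadscope_out"
    chrom_sizes: str | None = None
    calls_dir: str | None = None
    simulate_preset: str | None = None
    bin_size: int = 100_000
    nad_threshold: float = 0.20
    rdna_chroms: tuple[str, ...] = tuple(sorted(DEFAULT_RDNA_CHROMS))
    seed: int = 0
    n_cells: int | None = None
    subsample_sizes: tuple[int, ...] = (20, 30, 40)
    subsample_reps: int = 20
    bootstrap_iters: int = 1000
    cluster_k: int = 2
    run_structure: bool = True
    run_populations: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.nad_threshold < 1:
            raise ValidationError("nad_threshold must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in asdict(config).items()},
        "stages": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def stage(name: str):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        if config.simulate_preset:
            stage("simulate")
            sim = preset_config(config.simulate_preset, seed=config.seed,
                                n_cells=config.n_cells)
            truth = simulate_truth(sim)
            matrix, mat_m, mat_p = simulate_capture(truth, sim)
            write_cohort(matrix, truth, sim, out / "cohort",
                         maternal=mat_m, paternal=mat_p)
        elif config.calls_dir and config.chrom_sizes:
            stage("assemble")
            sizes = read_chrom_sizes(config.chrom_sizes)
            bins = build_bins(sizes, config.bin_size)
            beds = sorted(Path(config.calls_dir).glob("*.bed"))
            beds = [b for b in beds if ".maternal." not in b.name and ".paternal." not in b.name]
            if not beds:
                raise ValidationError(f"no BED files in {config.calls_dir}")
            matrix = read_cell_calls(beds, bins)
            mat_m = mat_p = None
        else:
            raise ValidationError("config needs either simulate_preset or calls_dir + chrom_sizes")

        write_matrix(matrix, out / "matrix")
        rdna = [c for c in config.rdna_chroms if c in matrix.bins.chrom_sizes]
        annotation = annotate(matrix.bins, rdna_chroms=rdna)

        stage("cf")
        cf = contact_frequency(matrix)
        write_cf_track(cf.cf, matrix.bins, out / "cf.bedgraph")

        stage("call")
        callset = call_nads(cf, config.nad_threshold)
        callset.to_bed(out / "nads.bed")
        callset.segments().to_csv(out / "nad_segments.tsv", sep="\t", index=False)

        stage("coverage")
        coverage = per_cell_coverage(matrix, callset)
        coverage.to_csv(out / "per_cell_coverage.tsv", sep="\t", index=False)

        stage("fpmodel")
        capture = float(coverage["raw"].mean())
        contamination_p = capture / 3.0  # one-third of captured content is noise
        model = false_positive_model(
            n=matrix.n_cells, p=contamination_p,
            threshold=config.nad_threshold, n_bins=matrix.bins.n_bins,
        )
        (out / "fp_model.json").write_text(json.dumps(model.report(), indent=2))

        if config.run_structure and matrix.n_cells >= 2:
            stage("structure")
            sizes_ok = [s for s in config.subsample_sizes if s < matrix.n_cells]
            if sizes_ok:
                sat = subsample_saturation(matrix, sizes=sizes_ok,
                                           reps=config.subsample_reps,
                                           seed=config.seed, threshold=config.nad_threshold)
                sat.to_csv(out / "saturation.tsv", sep="\t", index=False)
            q = yules_q(matrix)
            pd.DataFrame(q.q, index=q.cells, columns=q.cells).to_csv(
                out / "yules_q.tsv", sep="\t")
            curves = acf(matrix, max_lag=min(50, matrix.bins.n_bins // 4))
            fits = []
            for cell, curve in zip(matrix.cells, curves):
                x, _ = curve.finite()
                if x.size >= 3:
                    fit = fit_exponential(curve)
                    fits.append({"cell": cell, "a": fit.a, "b": fit.b,
                                 "residual_norm": fit.residual_norm})
            pd.DataFrame(fits).to_csv(out / "acf_fits.tsv", sep="\t", index=False)

        if config.run_populations and matrix.n_cells >= config.cluster_k:
            stage("populations")
            features = coverage_matrix(matrix, callset)
            result = diana(features, k=config.cluster_k)
            result.to_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)

        if mat_m is not None and mat_p is not None:
            stage("allelic")
            cf_m, cf_p = allelic_mod.allelic_cf(mat_m, mat_p)
            acs = allelic_mod.classify_allelic(cf_m, cf_p, config.nad_threshold)
            summary = allelic_mod.allelic_summaries(acs, annotation)
            (out / "allelic_summary.json").write_text(
                json.dumps(summary, indent=2, default=float))
    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "init"
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
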