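"""End-to-end orchestration: simulate (or load) -> DE -> inheritance -> ASE
-> cis/trans, with a manifest recording the seed and parameters.

Stage outputs are plain TSVs written through :func:`core_io.write_tables`;
identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import cistrans as ct_mod
from . import de as de_mod
from .core_io import ValidationError, write_tables
from .inheritance import classify_inheritance_table, inheritance_summary
from .simdata import SimConfig, simulate_trio_experiment

log = logging.getLogger("heterodiff")

DEFAULT_THRESHOLDS = {
    "min_fold": 2.0,       # DEG fold-change cutoff
    "fdr": 0.01,           # DEG BH-adjusted p cutoff
    "min_coverage": 10,    # hybrid reads per diagnostic SNP
    "inheritance_fold": 1.25,
    "alpha": 0.05,         # ASE balance / cis-trans test level
}


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    sim: SimConfig | None = None
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    stages: tuple[str, ...] = ("deg", "inheritance", "ase", "cistrans")
    all_genes: bool = False  # classify every gene, not just DEGs

    def __post_init__(self) -> None:
        for k, v in self.thresholds.items():
            if v <= 0:
                raise ValidationError(f"threshold {k} must be positive, got {v}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = {**DEFAULT_THRESHOLDS, **config.thresholds}

    sim_cfg = config.sim or SimConfig(seed=config.seed)
    t0 = time.perf_counter()
    sim = simulate_trio_experiment(sim_cfg)
    log.info("simulate: %d genes in %.1fs", sim_cfg.n_genes, time.perf_counter() - t0)
    trio, sheet, matrix = sim.trio, sim.sheet, sim.counts
    tables: dict[str, pd.DataFrame] = {
        "truth": sim.truth,
        "sample_sheet": sheet.df,
        "gene_counts": matrix.df.reset_index(),
        "allele_counts": sim.allele_counts.df,
    }

    deg_genes: set[str] = set()
    if "deg" in config.stages:
        t0 = time.perf_counter()
        de_results = []
        for parent in (trio.female_line, trio.male_line):
            res = de_mod.call_degs(
                matrix,
                sheet,
                (parent, trio.hybrid_line),
                fdr=th["fdr"],
                min_fold=th["min_fold"],
            )
            de_results.append(res)
            deg_genes |= set(res.loc[res["is_deg"], "gene_id"])
        de_all = pd.concat(de_results, ignore_index=True)
        tables["de_results"] = de_all
        tables["de_summary"] = de_mod.deg_summary(de_all)
        log.info("deg: %d DEG genes in %.1fs", len(deg_genes), time.perf_counter() - t0)

    factors = de_mod.size_factors(matrix)
    norm = de_mod.normalize_counts(matrix, factors)
    means = pd.DataFrame(
        {
            "FP": norm[sheet.samples_for_line(trio.female_line)].mean(axis=1),
            "MP": norm[sheet.samples_for_line(trio.male_line)].mean(axis=1),
            "HY": norm[sheet.samples_for_line(trio.hybrid_line)].mean(axis=1),
        }
    )

    inh_calls = None
    if "inheritance" in config.stages:
        t0 = time.perf_counter()
        universe = (
            means
            if (config.all_genes or "deg" not in config.stages)
            else means.loc[sorted(deg_genes)]
        )
        inh_calls = classify_inheritance_table(universe, fold=th["inheritance_fold"])
        tables["inheritance_calls"] = inh_calls.reset_index()
        summary = inheritance_summary(inh_calls) if not inh_calls.empty else None
        if summary is not None:
            tables["inheritance_summary"] = summary
        log.info("inheritance: %d genes in %.1fs", len(inh_calls), time.perf_counter() - t0)

    sums = ase_mod.gene_allele_counts(
        sim.allele_counts, sheet, trio, min_coverage=th["min_coverage"]
    )
    # put the two parental libraries on the hybrid's scale before the
    # parental-divergence and trans tests
    fp_med = factors[sheet.samples_for_line(trio.female_line)].to_numpy().mean()
    mp_med = factors[sheet.samples_for_line(trio.male_line)].to_numpy().mean()
    sums_norm = sums.copy()
    if not sums.empty:
        sums_norm["fp_par"] = np.round(sums["fp_par"] / fp_med).astype(np.int64)
        sums_norm["mp_par"] = np.round(sums["mp_par"] / mp_med).astype(np.int64)

    if "ase" in config.stages:
        t0 = time.perf_counter()
        ase_calls = ase_mod.relative_ase(sums, alpha=th["alpha"])
        tables["ase_calls"] = ase_calls
        tables["ase_bins"] = ase_mod.bin_ase(ase_calls)
        tables["ase_scatter"] = ase_mod.ase_scatter(sums)
        log.info("ase: %d genes in %.1fs", len(ase_calls), time.perf_counter() - t0)

    if "cistrans" in config.stages:
        t0 = time.perf_counter()
        tests = ct_mod.regulatory_tests(sums_norm)
        reg_calls = ct_mod.classify_regulatory(tests, alpha=th["alpha"])
        tables["regulatory_calls"] = reg_calls
        tables["regulatory_counts"] = ct_mod.category_counts(reg_calls)
        tables["regulatory_magnitudes"] = ct_mod.effect_magnitudes(reg_calls)
        tables["trans_factor_scatter"] = ct_mod.trans_factor_scatter(
            sums_norm, inh_calls
        )
        log.info("cistrans: %d genes in %.1fs", len(reg_calls), time.perf_counter() - t0)

    manifest_files = write_tables(tables, out)
    manifest = {
        "seed": config.seed,
        "thresholds": th,
        "stages": list(config.stages),
        "n_genes": sim_cfg.n_genes,
        "files": [p.name for p in manifest_files],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
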