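"""Ground-truth recovery evaluation for simulated trio experiments.

Runs the inference stages on a :class:`~heterodiff.simdata.SimResult`
and scores them against the generator's truth labels: the fraction of
cis-only / trans-only genes the regulatory classifier recovers, the
agreement of inheritance calls with the categories implied by the
generative means, and the false non-conserved rate under an
all-conserved simulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import cistrans as ct_mod
from . import de as de_mod
from .inheritance import classify_inheritance_table
from .simdata import SimResult


def normalized_allele_sums(sim: SimResult, min_coverage: int = 10) -> pd.DataFrame:
    """Per-gene allele sums with parental libraries scaled to the hybrid.

    Parental counts are divided by the mean size factor of that parent's
    libraries (median-of-ratios over the gene count matrix) and rounded,
    so tests comparing parental with hybrid-allelic counts see exposure-
    matched integers.
    """
    sums = ase_mod.gene_allele_counts(
        sim.allele_counts, sim.sheet, sim.trio, min_coverage=min_coverage
    )
    if sums.empty:
        return sums
    factors = de_mod.size_factors(sim.counts)
    fp_f = factors[sim.sheet.samples_for_line(sim.trio.female_line)].mean()
    mp_f = factors[sim.sheet.samples_for_line(sim.trio.male_line)].mean()
    out = sums.copy()
    out["fp_par"] = np.round(sums["fp_par"] / fp_f).astype(np.int64)
    out["mp_par"] = np.round(sums["mp_par"] / mp_f).astype(np.int64)
    return out


def regulatory_calls(sim: SimResult, alpha: float = 0.05) -> pd.DataFrame:
    """Classify regulatory divergence and join the truth labels."""
    sums = normalized_allele_sums(sim)
    calls = ct_mod.classify_regulatory(ct_mod.regulatory_tests(sums), alpha=alpha)
    return calls.merge(sim.truth, on="gene_id")


def regulatory_recovery(sim: SimResult, alpha: float = 0.05) -> dict[str, float]:
    """Per-label recovery fractions plus the overall non-conserved rate."""
    merged = regulatory_calls(sim, alpha=alpha)
    out: dict[str, float] = {}
    for label in merged["regulatory_label"].unique():
        sub = merged[merged["regulatory_label"] == label]
        out[label] = float((sub["category"] == label).mean())
    out["frac_non_conserved_calls"] = float((merged["category"] != "conserved").mean())
    return out


def inheritance_agreement(sim: SimResult) -> float:
    """Fraction of genes whose call matches the generative-mean category."""
    factors = de_mod.size_factors(sim.counts)
    norm = de_mod.normalize_counts(sim.counts, factors)
    means = pd.DataFrame(
        {
            "FP": norm[sim.sheet.samples_for_line(sim.trio.female_line)].mean(axis=1),
            "MP": norm[sim.sheet.samples_for_line(sim.trio.male_line)].mean(axis=1),
            "HY": norm[sim.sheet.samples_for_line(sim.trio.hybrid_line)].mean(axis=1),
        }
    )
    calls = classify_inheritance_table(means)
    truth = sim.truth.set_index("gene_id")["expected_inheritance"]
    return float((calls["category"] == truth.reindex(calls.index)).mean())
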