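"""Allele-specific expression: per-gene allele sums, relative ASE, bins.

Reads at parent-diagnostic SNPs are summed per gene (weighting sites by
coverage) after dropping sites whose hybrid coverage is below the
minimum.  Relative ASE is the percentage of hybrid reads carrying the
maternal (female-parent) allele,

.. math:: \\%FP_{HY} = 100 \\cdot FP_{HY} / (FP_{HY} + MP_{HY}),

tested against a balanced 1:1 split with a two-sided exact binomial test
(the one-sample exact equivalent of a 2x2 exact test against equal
proportions).  Genes are binned by maternal share into five bins,
left-closed/right-open with the final bin closed: [0,20), [20,40),
[40,60), [60,80), [80,100].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AlleleCountTable, SampleSheet, TrioDesign, ValidationError

BIN_LABELS = ("0-20", "20-40", "40-60", "60-80", "80-100")
BIN_EDGES = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)

MIN_COVERAGE = 10

SUM_COLUMNS = ["gene_id", "fp_hy", "mp_hy", "fp_par", "mp_par", "n_sites"]


def gene_allele_counts(
    act: AlleleCountTable,
    sheet: SampleSheet,
    trio: TrioDesign,
    min_coverage: int = MIN_COVERAGE,
) -> pd.DataFrame:
    """Sum allele counts per gene for one trio, applying the coverage filter.

    A site is kept when the summed hybrid coverage (maternal + paternal,
    over the hybrid's replicates) is at least ``min_coverage``.  Surviving
    sites contribute their hybrid allele counts and the parental counts
    at the same sites; genes with no surviving site are dropped.
    """
    hy_samples = set(sheet.samples_for_line(trio.hybrid_line))
    fp_samples = set(sheet.samples_for_line(trio.female_line))
    mp_samples = set(sheet.samples_for_line(trio.male_line))

    df = act.df
    hy = df[df["sample_id"].isin(hy_samples)]
    site_cov = hy.groupby(["gene_id", "chrom", "pos"])[
        ["maternal_count", "paternal_count"]
    ].sum()
    keep = site_cov[
        (site_cov["maternal_count"] + site_cov["paternal_count"]) >= min_coverage
    ].index
    if len(keep) == 0:
        return pd.DataFrame(columns=SUM_COLUMNS)

    keyed = df.set_index(["gene_id", "chrom", "pos"])
    kept = keyed.loc[keyed.index.isin(keep)].reset_index()

    def _sum(samples: set, col: str) -> pd.Series:
        sub = kept[kept["sample_id"].isin(samples)]
        return sub.groupby("gene_id")[col].sum()

    out = pd.DataFrame(
        {
            "fp_hy": _sum(hy_samples, "maternal_count"),
            "mp_hy": _sum(hy_samples, "paternal_count"),
            # parental libraries are single-allele: FP reads are maternal,
            # MP reads are paternal
            "fp_par": _sum(fp_samples, "maternal_count"),
            "mp_par": _sum(mp_samples, "paternal_count"),
        }
    ).fillna(0)
    n_sites = keep.to_frame(index=False).groupby("gene_id").size()
    out["n_sites"] = n_sites
    out = out.astype(np.int64).reset_index().rename(columns={"index": "gene_id"})
    return out[SUM_COLUMNS].sort_values("gene_id", kind="stable").reset_index(drop=True)


def balance_p_value(maternal: int, paternal: int) -> float:
    """Two-sided exact binomial p-value for a 1:1 allele split."""
    n = maternal + paternal
    if n == 0:
        raise ValidationError("zero total reads")
    return float(stats.binomtest(maternal, n, 0.5, alternative="two-sided").pvalue)


def assign_bin(pct_fp: float) -> str:
    """Five maternal-share bins, left-closed; 100 falls in the last bin."""
    if not 0.0 <= pct_fp <= 100.0:
        raise ValidationError(f"pct_fp {pct_fp} outside [0, 100]")
    idx = min(int(pct_fp // 20), len(BIN_LABELS) - 1)
    return BIN_LABELS[idx]


def relative_ase(sums: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene relative ASE with exact balance test and bin assignment."""
    if sums.empty:
        return pd.DataFrame(
            columns=SUM_COLUMNS + ["pct_fp", "p_balance", "significant", "bin"]
        )
    out = sums.copy()
    total = out["fp_hy"] + out["mp_hy"]
    out["pct_fp"] = 100.0 * out["fp_hy"] / total
    out["p_balance"] = [
        balance_p_value(int(m), int(p)) for m, p in zip(out["fp_hy"], out["mp_hy"])
    ]
    out["significant"] = out["p_balance"] < alpha
    out["bin"] = [assign_bin(x) for x in out["pct_fp"]]
    return out


def bin_ase(calls: pd.DataFrame) -> pd.DataFrame:
    """Bin counts over genes, plus the maternal-bias share (top two bins)."""
    counts = {label: 0 for label in BIN_LABELS}
    for b in calls.get("bin", []):
        counts[b] += 1
    total = sum(counts.values())
    out = pd.DataFrame(
        {"bin": list(BIN_LABELS), "count": [counts[b] for b in BIN_LABELS]}
    )
    out.attrs["maternal_bias_share"] = (
        (counts["60-80"] + counts["80-100"]) / total if total else 0.0
    )
    return out


def ase_scatter(sums: pd.DataFrame) -> pd.DataFrame:
    """Log-ratio coordinates: parental log2(FP/MP) vs hybrid log2(FP_HY/MP_HY).

    Genes with a zero count in any of the four sums are excluded (log
    undefined) and reported with a reason.
    """
    ok = (sums[["fp_hy", "mp_hy", "fp_par", "mp_par"]] > 0).all(axis=1)
    sub = sums[ok]
    return pd.DataFrame(
        {
            "gene_id": sub["gene_id"],
            "log2_parental_ratio": np.log2(sub["fp_par"] / sub["mp_par"]),
            "log2_hybrid_ratio": np.log2(sub["fp_hy"] / sub["mp_hy"]),
        }
    ).reset_index(drop=True)
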