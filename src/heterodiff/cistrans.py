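"""Cis/trans regulatory-divergence classification from allele counts.

Because both parental alleles of a hybrid share one cellular environment
(the same trans-acting factors), the allelic imbalance *within* the
hybrid measures the cis component alone, while the expression ratio
*between* the parents measures cis + trans.  Per gene:

* ``cis_mag   = log2(FP_HY / MP_HY)``
* ``trans_mag = log2(FP / MP) - log2(FP_HY / MP_HY)``

so ``cis_mag + trans_mag == log2(FP / MP)`` by construction.

Three two-sided tests are run per gene and BH-adjusted per test family
across all genes of a trio:

* **P** — parental divergence: is FP/(FP+MP) != 1/2?
* **C** — cis: is FP_HY/(FP_HY+MP_HY) != 1/2?
* **T** — trans: do the parental and hybrid-allelic proportions differ?

Small totals (< ``exact_threshold`` reads) use exact tests (binomial /
Fisher); larger totals use the chi-square two-proportion test.  The
category rules at level alpha:

==========================  =======================================
conserved                   none of P, C, T significant
cis_only                    P and C significant, T not
trans_only                  P and T significant, C not
cis_trans (enhancing)       C and T significant, same effect signs
cis_trans (compensating)    C and T significant, opposite signs
ambiguous                   any other pattern
==========================  =======================================
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ValidationError
from .de import benjamini_hochberg

EXACT_THRESHOLD = 200

CATEGORIES = (
    "conserved",
    "cis_only",
    "trans_only",
    "cis_trans_compensating",
    "cis_trans_enhancing",
    "ambiguous",
)

CALL_COLUMNS = [
    "gene_id",
    "p_parental",
    "p_cis",
    "p_trans",
    "adj_parental",
    "adj_cis",
    "adj_trans",
    "cis_mag",
    "trans_mag",
    "parental_mag",
    "category",
]


def _one_sample_test(k: int, n: int, exact_threshold: int) -> float:
    """Two-sided test of a count split against 1:1."""
    if n == 0:
        raise ValidationError("zero total")
    if n < exact_threshold:
        return float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
    chi2, p = stats.chisquare([k, n - k])[:2]
    return float(p)


def _two_sample_test(
    k1: int, n1: int, k2: int, n2: int, exact_threshold: int
) -> float:
    """Two-sided test of equality of two proportions k1/n1 vs k2/n2."""
    if n1 == 0 or n2 == 0:
        raise ValidationError("zero total")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if n1 + n2 < exact_threshold:
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if (table == 0).any():
        # chi2 with zero cells is unreliable; fall back to the exact test
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def regulatory_tests(
    sums: pd.DataFrame, exact_threshold: int = EXACT_THRESHOLD
) -> pd.DataFrame:
    """Raw p-values for tests P, C, T plus cis/trans magnitudes per gene.

    ``sums`` needs columns fp_par, mp_par, fp_hy, mp_hy (parental counts
    already on a comparable scale, e.g. size-factor normalized and
    rounded).  Genes with a zero side total are excluded.
    """
    ok = ((sums["fp_par"] + sums["mp_par"]) > 0) & ((sums["fp_hy"] + sums["mp_hy"]) > 0)
    sub = sums[ok].reset_index(drop=True)
    p_par, p_cis, p_trans = [], [], []
    for r in sub.itertuples(index=False):
        p_par.append(
            _one_sample_test(int(r.fp_par), int(r.fp_par + r.mp_par), exact_threshold)
        )
        p_cis.append(
            _one_sample_test(int(r.fp_hy), int(r.fp_hy + r.mp_hy), exact_threshold)
        )
        p_trans.append(
            _two_sample_test(
                int(r.fp_par),
                int(r.fp_par + r.mp_par),
                int(r.fp_hy),
                int(r.fp_hy + r.mp_hy),
                exact_threshold,
            )
        )
    # 0.5-read continuity offset keeps the log ratios finite at zero counts
    cis_mag = np.log2((sub["fp_hy"] + 0.5) / (sub["mp_hy"] + 0.5))
    parental_mag = np.log2((sub["fp_par"] + 0.5) / (sub["mp_par"] + 0.5))
    out = sub[["gene_id"]].copy()
    out["p_parental"] = p_par
    out["p_cis"] = p_cis
    out["p_trans"] = p_trans
    out["cis_mag"] = cis_mag.to_numpy()
    out["trans_mag"] = (parental_mag - cis_mag).to_numpy()
    out["parental_mag"] = parental_mag.to_numpy()
    return out


def _categorize(sig_p: bool, sig_c: bool, sig_t: bool, cis: float, trans: float) -> str:
    if sig_c and sig_t:
        return (
            "cis_trans_enhancing"
            if np.sign(cis) == np.sign(trans)
            else "cis_trans_compensating"
        )
    if not (sig_p or sig_c or sig_t):
        return "conserved"
    if sig_p and sig_c and not sig_t:
        return "cis_only"
    if sig_p and sig_t and not sig_c:
        return "trans_only"
    return "ambiguous"


def classify_regulatory(
    tests: pd.DataFrame, alpha: float = 0.05, fold_ambiguous: bool = False
) -> pd.DataFrame:
    """BH-adjust the three test families and assign regulatory categories.

    ``fold_ambiguous=True`` reassigns ambiguous genes to the nearest of
    the five primary categories (largest significant-magnitude effect,
    defaulting to conserved) for figure parity with five-category
    summaries.
    """
    out = tests.copy()
    for col in ("parental", "cis", "trans"):
        out[f"adj_{col}"] = benjamini_hochberg(out[f"p_{col}"].to_numpy())
    sig_p = out["adj_parental"] <= alpha
    sig_c = out["adj_cis"] <= alpha
    sig_t = out["adj_trans"] <= alpha
    out["category"] = [
        _categorize(p, c, t, cm, tm)
        for p, c, t, cm, tm in zip(
            sig_p, sig_c, sig_t, out["cis_mag"], out["trans_mag"]
        )
    ]
    if fold_ambiguous:
        amb = out["category"] == "ambiguous"
        folded = np.where(
            sig_c[amb],
            "cis_only",
            np.where(sig_t[amb], "trans_only", "conserved"),
        )
        out.loc[amb, "category"] = folded
    return out[
        [c for c in CALL_COLUMNS if c in out.columns]
    ].reset_index(drop=True)


def effect_magnitudes(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-category quartiles of |log2(FP/MP)|, plus overall cis/trans medians.

    Categories with no genes are absent from the output rather than
    reported as zero.
    """
    rows = []
    for cat in CATEGORIES:
        sub = calls[calls["category"] == cat]
        if sub.empty:
            continue
        mags = sub["parental_mag"].abs()
        rows.append(
            {
                "category": cat,
                "n": len(sub),
                "q25": float(mags.quantile(0.25)),
                "median": float(mags.median()),
                "q75": float(mags.quantile(0.75)),
            }
        )
    out = pd.DataFrame(rows, columns=["category", "n", "q25", "median", "q75"])
    out.attrs["median_abs_cis"] = float(calls["cis_mag"].abs().median())
    out.attrs["median_abs_trans"] = float(calls["trans_mag"].abs().median())
    return out


def category_counts(calls: pd.DataFrame) -> pd.DataFrame:
    counts = calls["category"].value_counts()
    total = len(calls)
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [int(counts.get(c, 0)) for c in CATEGORIES],
            "pct": [
                100.0 * int(counts.get(c, 0)) / total if total else 0.0
                for c in CATEGORIES
            ],
        }
    )


def trans_factor_scatter(
    sums: pd.DataFrame,
    inheritance_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Allele-level expression change of each parental genome in the hybrid.

    x = log2(2 * MP_HY / MP), y = log2(2 * FP_HY / FP): how much each
    parent's allele moved between the parent and the hybrid.  The factor
    2 makes one hybrid allele comparable to a whole single-parent
    library (a conserved gene splits its hybrid expression evenly across
    the two alleles).  Counts must be on a comparable (normalized)
    scale.  Genes with any zero denominator or zero allele count are
    excluded.  If inheritance calls are given (indexed by gene), their
    category is joined for quadrant cross-tabulation.
    """
    ok = (sums[["fp_hy", "mp_hy", "fp_par", "mp_par"]] > 0).all(axis=1)
    sub = sums[ok]
    out = pd.DataFrame(
        {
            "gene_id": sub["gene_id"],
            "x_mp": np.log2(2.0 * sub["mp_hy"] / sub["mp_par"]),
            "y_fp": np.log2(2.0 * sub["fp_hy"] / sub["fp_par"]),
        }
    ).reset_index(drop=True)
    if inheritance_calls is not None:
        out = out.merge(
            inheritance_calls[["category"]],
            left_on="gene_id",
            right_index=True,
            how="left",
        )
    return out


def scatter_quadrant_crosstab(scatter: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate scatter quadrants against inheritance categories."""
    if "category" not in scatter.columns:
        raise ValidationError("scatter lacks inheritance categories")
    quad = np.where(
        scatter["x_mp"] >= 0,
        np.where(scatter["y_fp"] >= 0, "x+y+", "x+y-"),
        np.where(scatter["y_fp"] >= 0, "x-y+", "x-y-"),
    )
    tab = (
        pd.DataFrame({"quadrant": quad, "category": scatter["category"]})
        .groupby(["category", "quadrant"], dropna=False)
        .size()
        .rename("count")
        .reset_index()
    )
    return tab
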