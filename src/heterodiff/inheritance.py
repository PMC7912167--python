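"""Expression-inheritance classification for hybrid/parent trios.

Each gene's hybrid expression is compared to its two parents on the log2
scale.  With a pseudocount of 1 and threshold ``tau = log2(1.25)``:

* ``dF = log2(HY + 1) - log2(FP + 1)``  (deviation from the female parent)
* ``dM = log2(HY + 1) - log2(MP + 1)``  (deviation from the male parent)

A hybrid within ``tau`` of both parents is *conserved*.  Otherwise the
gene is assigned one of eight divergent categories:

=====  =============================================
I      additive, FP > MP (hybrid at mid-parent level)
II     additive, MP > FP
III    paternal low-parent dominance  (HY ~ MP < FP)
IV     paternal high-parent dominance (HY ~ MP > FP)
V      maternal low-parent dominance  (HY ~ FP < MP)
VI     maternal high-parent dominance (HY ~ FP > MP)
VII    transgressive up   (HY above both parents)
VIII   transgressive down (HY below both parents)
=====  =============================================

Additive genes must deviate more than ``tau`` from *both* parents while
lying strictly between them; a hybrid within ``tau`` of both parents is
conserved even when the parents differ by more than ``tau`` (that
residual cell is flagged ``ambiguous_conserved``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import ValidationError

DEFAULT_FOLD = 1.25

CATEGORIES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "conserved")

CATEGORY_LABELS = {
    "I": "additive (FP > MP)",
    "II": "additive (MP > FP)",
    "III": "paternal low-parent dominance",
    "IV": "paternal high-parent dominance",
    "V": "maternal low-parent dominance",
    "VI": "maternal high-parent dominance",
    "VII": "transgressive up",
    "VIII": "transgressive down",
    "conserved": "conserved",
}

DOMINANT = ("III", "IV", "V", "VI")
MATERNAL_DOMINANT = ("V", "VI")
TRANSGRESSIVE = ("VII", "VIII")
ADDITIVE = ("I", "II")


def classify_inheritance(
    expr_fp: float, expr_mp: float, expr_hy: float, fold: float = DEFAULT_FOLD
) -> str:
    """Classify one gene from normalized mean expressions (>= 0)."""
    if min(expr_fp, expr_mp, expr_hy) < 0:
        raise ValidationError("expressions must be non-negative")
    tau = np.log2(fold)
    d_f = np.log2(expr_hy + 1.0) - np.log2(expr_fp + 1.0)
    d_m = np.log2(expr_hy + 1.0) - np.log2(expr_mp + 1.0)
    fp_gt_mp = d_m > d_f  # log2(FP+1) > log2(MP+1)

    if abs(d_f) <= tau and abs(d_m) <= tau:
        return "conserved"
    if d_f > tau and d_m > tau:
        return "VII"
    if d_f < -tau and d_m < -tau:
        return "VIII"
    if abs(d_f) <= tau:  # hybrid tracks the female parent
        return "VI" if fp_gt_mp else "V"
    if abs(d_m) <= tau:  # hybrid tracks the male parent
        return "IV" if not fp_gt_mp else "III"
    # deviates > tau from both parents, strictly between them -> additive
    return "I" if fp_gt_mp else "II"


def classify_inheritance_table(
    expr: pd.DataFrame, fold: float = DEFAULT_FOLD
) -> pd.DataFrame:
    """Vectorized classification; ``expr`` has columns FP, MP, HY indexed by gene.

    Returns per-gene deviations dF, dM, the parental divergence dP and the
    category, plus the ``ambiguous_conserved`` flag for conserved calls
    whose parents differ by more than the threshold.
    """
    if (expr[["FP", "MP", "HY"]] < 0).any().any():
        raise ValidationError("expressions must be non-negative")
    tau = np.log2(fold)
    l_fp = np.log2(expr["FP"].to_numpy(dtype=float) + 1.0)
    l_mp = np.log2(expr["MP"].to_numpy(dtype=float) + 1.0)
    l_hy = np.log2(expr["HY"].to_numpy(dtype=float) + 1.0)
    d_f = l_hy - l_fp
    d_m = l_hy - l_mp
    d_p = l_fp - l_mp
    fp_gt_mp = d_p > 0

    cat = np.full(len(expr), "conserved", dtype=object)
    near_f = np.abs(d_f) <= tau
    near_m = np.abs(d_m) <= tau
    up = (d_f > tau) & (d_m > tau)
    down = (d_f < -tau) & (d_m < -tau)
    maternal = near_f & ~near_m & ~up & ~down
    paternal = near_m & ~near_f & ~up & ~down
    additive = ~near_f & ~near_m & ~up & ~down

    cat[up] = "VII"
    cat[down] = "VIII"
    cat[maternal & fp_gt_mp] = "VI"
    cat[maternal & ~fp_gt_mp] = "V"
    cat[paternal & ~fp_gt_mp] = "IV"
    cat[paternal & fp_gt_mp] = "III"
    cat[additive & fp_gt_mp] = "I"
    cat[additive & ~fp_gt_mp] = "II"

    return pd.DataFrame(
        {
            "gene_id": expr.index,
            "dF": d_f,
            "dM": d_m,
            "dP": d_p,
            "category": cat,
            "ambiguous_conserved": (cat == "conserved") & (np.abs(d_p) > tau),
        }
    ).set_index("gene_id")


def inheritance_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Category counts plus derived shares.

    Shares reported: additive, dominant (III–VI) and transgressive as
    fractions of non-conserved calls, and the maternal share of the
    dominant calls, (V+VI)/(III+IV+V+VI).
    """
    if calls.empty:
        raise ValidationError("no calls to summarize")
    counts = calls["category"].value_counts()
    n = {c: int(counts.get(c, 0)) for c in CATEGORIES}
    divergent = sum(n[c] for c in CATEGORIES if c != "conserved")
    dominant = sum(n[c] for c in DOMINANT)
    rows = [
        {"category": c, "label": CATEGORY_LABELS[c], "count": n[c]}
        for c in CATEGORIES
    ]
    out = pd.DataFrame(rows, columns=["category", "label", "count"])
    shares = {
        "pct_additive": 100.0 * sum(n[c] for c in ADDITIVE) / divergent
        if divergent
        else 0.0,
        "pct_dominant": 100.0 * dominant / divergent if divergent else 0.0,
        "pct_transgressive": 100.0 * sum(n[c] for c in TRANSGRESSIVE) / divergent
        if divergent
        else 0.0,
        "pct_maternal_of_dominant": 100.0
        * sum(n[c] for c in MATERNAL_DOMINANT)
        / dominant
        if dominant
        else 0.0,
    }
    out.attrs["shares"] = shares
    return out
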