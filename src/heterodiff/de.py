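"""Count normalization and differential-expression calling.

Normalization is median-of-ratios: each sample's size factor is the
median, over genes expressed in every sample, of that sample's count
divided by the gene's geometric mean across samples.

The per-gene test is a Welch two-sample t-test on ``log2(normalized + 1)``
replicate values, with Benjamini–Hochberg adjustment across genes.  This
is an explicit stand-in for a negative-binomial exact test: it keeps the
decision rule (adjusted p <= 0.01 and fold change >= 2 by default) while
trading the NB dispersion model for a simpler test on log counts.  Genes
whose replicates are identical on both sides carry no evidence and get
p = 1.  Genes with fewer than two replicates per side are rejected.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneCountMatrix, SampleSheet, ValidationError

DE_COLUMNS = [
    "gene_id",
    "comparison",
    "log2_fold_change",
    "p_value",
    "adjusted_p",
    "is_deg",
    "direction",
]


def size_factors(m: GeneCountMatrix) -> pd.Series:
    """Median-of-ratios size factors, one per sample."""
    counts = m.df.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError("no gene has nonzero counts in every sample")
    sub = counts[all_pos]
    log_geomean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geomean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=m.sample_ids, name="size_factor")


def normalize_counts(m: GeneCountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor (real-valued output)."""
    factors = factors.reindex(m.sample_ids)
    if factors.isna().any():
        raise ValidationError("size factors missing for some samples")
    return m.df / factors


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch p-values per row; zero-variance rows give p = 1."""
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    return np.where(np.isnan(p), 1.0, p)


def call_degs(
    m: GeneCountMatrix,
    sheet: SampleSheet,
    comparison: tuple[str, str],
    fdr: float = 0.01,
    min_fold: float = 2.0,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Call DEGs between two lines.

    ``comparison`` is (line_a, line_b); the fold change and direction are
    relative to line_b (``up`` means higher in line_b), matching the
    reading of a "line_a vs. line_b" contrast where line_b is the hybrid.
    By default normalization is computed over just the samples of the two
    lines; pass ``factors`` for global normalization.
    """
    line_a, line_b = comparison
    samples_a = sheet.samples_for_line(line_a)
    samples_b = sheet.samples_for_line(line_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError("each side of a comparison needs >= 2 replicates")

    pair = m.subset_samples(samples_a + samples_b)
    if factors is None:
        factors = size_factors(pair)
    norm = normalize_counts(pair, factors)

    a = np.log2(norm[samples_a].to_numpy() + 1.0)
    b = np.log2(norm[samples_b].to_numpy() + 1.0)
    p = _welch_p(a, b)

    mean_a = norm[samples_a].mean(axis=1).to_numpy()
    mean_b = norm[samples_b].mean(axis=1).to_numpy()
    lfc = np.log2(mean_b + 1.0) - np.log2(mean_a + 1.0)

    adj = benjamini_hochberg(p)
    min_lfc = np.log2(min_fold)
    is_deg = (adj <= fdr) & (np.abs(lfc) >= min_lfc)
    return pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "comparison": f"{line_a} vs {line_b}",
            "log2_fold_change": lfc,
            "p_value": p,
            "adjusted_p": adj,
            "is_deg": is_deg,
            "direction": np.where(lfc >= 0, "up", "down"),
        },
        columns=DE_COLUMNS,
    )


def deg_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per-comparison DEG totals with up/down split (total = up + down)."""
    rows = []
    for comp, grp in results.groupby("comparison", sort=True):
        degs = grp[grp["is_deg"]]
        up = int((degs["direction"] == "up").sum())
        down = int((degs["direction"] == "down").sum())
        rows.append(
            {"comparison": comp, "n_deg": up + down, "up": up, "down": down}
        )
    return pd.DataFrame(rows, columns=["comparison", "n_deg", "up", "down"])


def deg_overlap(deg_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Counts for every intersection region of up to four DEG sets.

    Each region is the set of genes inside a given subset of the input
    sets and outside all the others; regions partition the union.
    """
    if len(deg_sets) < 2:
        raise ValidationError("need at least two sets")
    if len(deg_sets) > 4:
        raise ValidationError("at most four sets supported")
    names = sorted(deg_sets)
    universe = set().union(*deg_sets.values())
    region_counts: dict[tuple[bool, ...], int] = {
        pattern: 0 for pattern in product([False, True], repeat=len(names))
    }
    for gene in universe:
        pattern = tuple(gene in deg_sets[n] for n in names)
        region_counts[pattern] += 1
    rows = []
    for pattern, count in region_counts.items():
        if not any(pattern):
            continue
        rows.append(
            {
                "region": "&".join(n for n, inc in zip(names, pattern) if inc),
                "exclusive_count": count,
            }
        )
    out = pd.DataFrame(rows, columns=["region", "exclusive_count"])
    return out.sort_values("region", kind="stable").reset_index(drop=True)
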