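"""Record-level variant hard filters, parent-diagnostic SNP selection, and
hybrid-vs-parent consistency categories.

The hard filter removes a record when any of these holds:

* ``QUAL < 30``
* ``QD < 5.0``
* ``HRun > 5``
* ``MQ0 >= 4`` **and** ``MQ0 / DP > 0.1``
* the record is a SNP inside a 10-bp window containing >= 3 SNPs
  (sliding cluster filter)

A record whose INFO lacks a key is not tested against that key's
threshold — "field absent" passes, distinct from "fails threshold" — and
is flagged ``untested`` in the returned set.

Hybrid variants are partitioned by presence of the same (chrom, pos, alt)
allele in the parents: in neither parent (hybrid-specific), in both, in
the male parent only, or in the female parent only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import TrioDesign, ValidationError, VariantSet

CATEGORIES = (
    "hybrid_specific",
    "consistent_both",
    "consistent_male",
    "consistent_female",
)

CLUSTER_WINDOW = 10  # bp
CLUSTER_MIN_SNPS = 3


def _cluster_mask(df: pd.DataFrame) -> np.ndarray:
    """True for SNPs lying in any 10-bp window holding >= 3 SNPs."""
    mask = np.zeros(len(df), dtype=bool)
    snp = df[df["vtype"] == "snp"]
    for _, grp in snp.groupby("chrom"):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos_sorted = pos[order]
        idx_sorted = grp.index.to_numpy()[order]
        k = CLUSTER_MIN_SNPS
        for i in range(len(pos_sorted) - k + 1):
            if pos_sorted[i + k - 1] - pos_sorted[i] <= CLUSTER_WINDOW - 1:
                mask[idx_sorted[i : i + k]] = True
    return mask


def hard_filter_variants(vs: VariantSet) -> VariantSet:
    """Apply the record-level hard filters; return the surviving records.

    Adds an ``untested`` boolean column: True when at least one filter
    criterion could not be evaluated because its INFO key was absent.
    """
    df = vs.df.reset_index(drop=True)

    qual = df["qual"].to_numpy(dtype=float)
    qd = df["QD"].to_numpy(dtype=float)
    hrun = df["HRun"].to_numpy(dtype=float)
    mq0 = df["MQ0"].to_numpy(dtype=float)
    dp = df["DP"].to_numpy(dtype=float)

    # NaN (absent field) compares False against every threshold, so an
    # absent key passes that criterion by construction
    with np.errstate(invalid="ignore", divide="ignore"):
        fail = (
            (qual < 30.0)
            | (qd < 5.0)
            | (hrun > 5.0)
            | ((mq0 >= 4.0) & (mq0 / dp > 0.1))
        )
    fail |= _cluster_mask(df)

    untested = (
        np.isnan(qual)
        | np.isnan(qd)
        | np.isnan(hrun)
        | np.isnan(mq0)
        | np.isnan(dp)
    )

    kept = df.loc[~fail].copy()
    kept["untested"] = untested[~fail]
    return VariantSet(kept, vs.line_ids)


def diagnostic_snps(vs: VariantSet, trio: TrioDesign) -> pd.DataFrame:
    """Select parent-diagnostic SNP sites for a trio.

    Keeps SNP records where the two parents are homozygous for different
    alleles (one hom_ref, the other hom_alt), so hybrid reads at the site
    are assignable to a parent of origin.  Heterozygous or missing calls
    in either parent exclude the site.
    """
    fp_gt = vs.genotype(trio.female_line)
    mp_gt = vs.genotype(trio.male_line)
    df = vs.df
    is_snp = df["vtype"] == "snp"
    opposite = ((fp_gt == "hom_ref") & (mp_gt == "hom_alt")) | (
        (fp_gt == "hom_alt") & (mp_gt == "hom_ref")
    )
    out = df.loc[is_snp & opposite, ["chrom", "pos", "ref", "alt"]].copy()
    out["maternal_allele"] = np.where(
        fp_gt.loc[out.index] == "hom_alt", out["alt"], out["ref"]
    )
    out["paternal_allele"] = np.where(
        out["maternal_allele"] == out["alt"], out["ref"], out["alt"]
    )
    return out.reset_index(drop=True)


def _alt_keys(vs: VariantSet, vtype: str) -> set[tuple]:
    df = vs.df
    sel = df[df["vtype"] == vtype]
    return set(zip(sel["chrom"], sel["pos"], sel["alt"]))


def categorize_variants(
    hybrid_vs: VariantSet,
    fp_vs: VariantSet,
    mp_vs: VariantSet,
    trio: TrioDesign,
) -> pd.DataFrame:
    """Assign each hybrid variant to exactly one parental-consistency category.

    Matching requires identical chrom, pos and alt allele; genotype
    zygosity is ignored.  Returns one summary row per variant type with
    category counts and percentages of the hybrid total.
    """
    rows = []
    for vtype in ("snp", "indel"):
        hy = _alt_keys(hybrid_vs, vtype)
        fp = _alt_keys(fp_vs, vtype)
        mp = _alt_keys(mp_vs, vtype)
        counts = {
            "hybrid_specific": len(hy - fp - mp),
            "consistent_both": len(hy & fp & mp),
            "consistent_male": len((hy & mp) - fp),
            "consistent_female": len((hy & fp) - mp),
        }
        total = len(hy)
        assert sum(counts.values()) == total  # partition invariant
        row = {"trio": trio.hybrid_line, "vtype": vtype, "total": total}
        row.update(counts)
        for cat in CATEGORIES:
            row[f"{cat}_pct"] = 100.0 * counts[cat] / total if total else 0.0
        rows.append(row)
    cols = (
        ["trio", "vtype", "total"]
        + list(CATEGORIES)
        + [f"{c}_pct" for c in CATEGORIES]
    )
    return pd.DataFrame(rows, columns=cols)


def summarize_category_counts(
    counts: dict[str, int], total: int, trio: str = "", vtype: str = ""
) -> pd.DataFrame:
    """Summary row from pre-tabulated category counts and a stated total.

    Useful when category counts come from an external tabulation whose
    grand total is reported separately (the counts need not sum to it);
    percentages are taken against the stated total.
    """
    unknown = sorted(set(counts) - set(CATEGORIES))
    if unknown:
        raise ValidationError(f"unknown categories: {unknown}")
    if total <= 0:
        raise ValidationError("total must be positive")
    row = {"trio": trio, "vtype": vtype, "total": total}
    for cat in CATEGORIES:
        n = int(counts.get(cat, 0))
        row[cat] = n
        row[f"{cat}_pct"] = 100.0 * n / total
    cols = (
        ["trio", "vtype", "total"]
        + list(CATEGORIES)
        + [f"{c}_pct" for c in CATEGORIES]
    )
    return pd.DataFrame([row], columns=cols)
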