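"""Readers, writers and validation for the tabular formats the pipeline touches.

Containers are thin wrappers around :class:`pandas.DataFrame` with
validation at construction time.  Coordinates are 1-based inclusive (VCF
convention).  Gene count matrices hold raw integer read counts only;
normalized, real-valued expression always lives in a separate table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

ROLES = ("female_parent", "male_parent", "hybrid")

GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class TrioDesign:
    """One cross: a hybrid line and its female (seed) and male (pollen) parent lines."""

    hybrid_line: str
    female_line: str
    male_line: str

    def __post_init__(self) -> None:
        if self.female_line == self.male_line:
            raise ValidationError(
                f"trio {self.hybrid_line}: female and male parent are both "
                f"{self.female_line!r}"
            )

    @property
    def lines(self) -> tuple[str, str, str]:
        return (self.female_line, self.male_line, self.hybrid_line)


class SampleSheet:
    """Maps sequencing samples to lines and roles.

    Columns: ``sample_id``, ``line_id``, ``role`` (one of female_parent,
    male_parent, hybrid) and ``replicate`` (positive integer).
    """

    COLUMNS = ["sample_id", "line_id", "role", "replicate"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        df = df[self.COLUMNS].copy()
        df["replicate"] = df["replicate"].astype(int)
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        bad_roles = sorted(set(df["role"]) - set(ROLES))
        if bad_roles:
            raise ValidationError(f"unknown roles {bad_roles}; expected one of {ROLES}")
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate numbers must be positive")
        self.df = df.sort_values("sample_id", kind="stable").reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def line_ids(self) -> list[str]:
        return sorted(self.df["line_id"].unique())

    def samples_for_line(self, line_id: str) -> list[str]:
        sel = self.df.loc[self.df["line_id"] == line_id, "sample_id"]
        if sel.empty:
            raise ValidationError(f"line {line_id!r} has no samples in the sheet")
        return sel.tolist()

    def role_of_line(self, line_id: str) -> str:
        roles = self.df.loc[self.df["line_id"] == line_id, "role"].unique()
        if len(roles) != 1:
            raise ValidationError(f"line {line_id!r} maps to roles {sorted(roles)}")
        return roles[0]


class GeneCountMatrix:
    """Integer read counts, genes in rows, samples in columns."""

    def __init__(self, counts: pd.DataFrame):
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        self.df = counts.sort_index(kind="stable")

    @property
    def gene_ids(self) -> list[str]:
        return self.df.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.df.columns.tolist()

    def subset_samples(self, sample_ids: Iterable[str]) -> "GeneCountMatrix":
        return GeneCountMatrix(self.df[list(sample_ids)])


class VariantSet:
    """A set of variant records with per-line genotype calls.

    One row per record: ``chrom``, ``pos`` (1-based), ``ref``, ``alt``,
    ``qual``, the INFO keys ``QD``, ``HRun``, ``MQ0``, ``DP`` (NaN when the
    key is absent from the record — absent is distinct from zero), a
    ``vtype`` of ``snp``/``indel`` derived from allele lengths, and one
    ``gt_<line>`` column per requested line.
    """

    INFO_KEYS = ("QD", "HRun", "MQ0", "DP")

    def __init__(self, df: pd.DataFrame, line_ids: list[str]):
        required = ["chrom", "pos", "ref", "alt", "qual", "vtype"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"variant table missing columns: {missing}")
        if (df["pos"] < 1).any():
            raise ValidationError("positions must be >= 1")
        if (df["ref"] == df["alt"]).any():
            raise ValidationError("ref and alt alleles must differ")
        self.line_ids = list(line_ids)
        self.df = df.sort_values(["chrom", "pos", "alt"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    def genotype(self, line_id: str) -> pd.Series:
        col = f"gt_{line_id}"
        if col not in self.df.columns:
            raise ValidationError(f"no genotypes for line {line_id!r}")
        return self.df[col]


def _vtype(ref: str, alt: str) -> str:
    return "snp" if len(ref) == 1 and len(alt) == 1 else "indel"


def _gt_code(gt: tuple) -> str:
    alleles = [a for a in gt if a is not None]
    if not alleles or len(alleles) < len(gt):
        return "missing"
    if all(a == 0 for a in alleles):
        return "hom_ref"
    if all(a > 0 for a in alleles) and len(set(alleles)) == 1:
        return "hom_alt"
    return "het"


def load_variants(vcf_path: str | os.PathLike, line_ids: list[str]) -> VariantSet:
    """Load a VCF (4.x, plain text or bgzipped) into a :class:`VariantSet`.

    Only the fields the downstream hard filter and diagnostic-SNP selection
    need are retained.  Multi-allelic records are split into one row per
    alternate allele; genotypes are coded against that allele.
    """
    with pysam.VariantFile(str(vcf_path)) as vf:
        header_samples = list(vf.header.samples)
        absent = [l for l in line_ids if l not in header_samples]
        if absent:
            raise ValidationError(
                f"lines {absent} not in VCF header (has {header_samples})"
            )
        rows = []
        for rec_no, rec in enumerate(vf, start=1):
            try:
                alts = rec.alts or ()
                for alt_idx, alt in enumerate(alts, start=1):
                    row = {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alt,
                        "qual": np.nan if rec.qual is None else float(rec.qual),
                        "vtype": _vtype(rec.ref, alt),
                    }
                    for key in VariantSet.INFO_KEYS:
                        val = rec.info.get(key)
                        if isinstance(val, tuple):
                            val = val[0]
                        row[key] = np.nan if val is None else float(val)
                    for line in line_ids:
                        gt = rec.samples[line].get("GT", (None,))
                        code = _gt_code(gt)
                        # recode against this alt allele: a hom call for a
                        # different alt is not a hom call for this one
                        if code == "hom_alt":
                            called = {a for a in gt if a}
                            if called != {alt_idx}:
                                code = "het" if alt_idx in called else "hom_ref"
                        row[f"gt_{line}"] = code
                    rows.append(row)
            except ValidationError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with record number
                raise ValidationError(
                    f"malformed VCF record #{rec_no} in {vcf_path}: {exc}"
                ) from exc
    columns = (
        ["chrom", "pos", "ref", "alt", "qual", "vtype"]
        + list(VariantSet.INFO_KEYS)
        + [f"gt_{l}" for l in line_ids]
    )
    df = pd.DataFrame(rows, columns=columns)
    return VariantSet(df, line_ids)


class AlleleCountTable:
    """Maternal/paternal read counts at parent-diagnostic SNP sites.

    Columns: ``gene_id``, ``chrom``, ``pos``, ``sample_id``,
    ``maternal_count``, ``paternal_count``.  (gene, pos, sample) is unique.
    Hybrid samples carry both allele counts; parental samples are single-
    allele by construction (a female-parent library is all-maternal).
    """

    COLUMNS = ["gene_id", "chrom", "pos", "sample_id", "maternal_count", "paternal_count"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"allele count table missing columns: {missing}")
        df = df[self.COLUMNS].copy()
        for c in ("maternal_count", "paternal_count"):
            df[c] = df[c].astype(np.int64)
            if (df[c] < 0).any():
                raise ValidationError(f"{c} must be non-negative")
        key = ["gene_id", "pos", "sample_id"]
        if df.duplicated(subset=key).any():
            raise ValidationError("duplicate (gene, pos, sample) rows")
        self.df = df.sort_values(
            ["gene_id", "chrom", "pos", "sample_id"], kind="stable"
        ).reset_index(drop=True)


class TraitTable:
    """Block-level trait measurements per line.

    Columns: ``line_id``, ``block`` (integer replicate-block), ``trait``,
    ``value``.  Size/weight traits must be positive.
    """

    COLUMNS = ["line_id", "block", "trait", "value"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"trait table missing columns: {missing}")
        df = df[self.COLUMNS].copy()
        df["block"] = df["block"].astype(int)
        df["value"] = df["value"].astype(float)
        self.df = df.sort_values(
            ["trait", "line_id", "block"], kind="stable"
        ).reset_index(drop=True)

    def line_mean(self, line_id: str, trait: str) -> float:
        sel = self.df[(self.df["line_id"] == line_id) & (self.df["trait"] == trait)]
        if sel.empty:
            raise ValidationError(f"no values for line {line_id!r}, trait {trait!r}")
        return float(sel["value"].mean())


def load_trios(trio_path: str | os.PathLike) -> list[TrioDesign]:
    df = pd.read_csv(trio_path)
    required = ["hybrid_line", "female_line", "male_line"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"trio file missing columns: {missing}")
    return [
        TrioDesign(r.hybrid_line, r.female_line, r.male_line)
        for r in df.itertuples(index=False)
    ]


def load_inputs(
    counts_path: str | os.PathLike,
    sample_sheet_path: str | os.PathLike,
    trio_path: str | os.PathLike,
) -> tuple[GeneCountMatrix, SampleSheet, list[TrioDesign]]:
    """Load and cross-validate the count matrix, sample sheet and trio design."""
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    matrix = GeneCountMatrix(counts)
    sheet = SampleSheet(pd.read_csv(sample_sheet_path))
    trios = load_trios(trio_path)

    in_counts, in_sheet = set(matrix.sample_ids), set(sheet.sample_ids)
    only_sheet = sorted(in_sheet - in_counts)
    if only_sheet:
        raise ValidationError(f"samples in sheet but not in counts: {only_sheet}")
    only_counts = sorted(in_counts - in_sheet)
    if only_counts:
        raise ValidationError(f"samples in counts but not in sheet: {only_counts}")

    known_lines = set(sheet.line_ids)
    for trio in trios:
        unknown = [l for l in trio.lines if l not in known_lines]
        if unknown:
            raise ValidationError(
                f"trio {trio.hybrid_line}: lines {unknown} absent from sample sheet"
            )
    return matrix, sheet, trios


def load_allele_counts(path: str | os.PathLike) -> AlleleCountTable:
    return AlleleCountTable(pd.read_csv(path, sep="\t"))


def load_traits(path: str | os.PathLike) -> TraitTable:
    return TraitTable(pd.read_csv(path))


def write_tables(
    results: Mapping[str, pd.DataFrame], out_dir: str | os.PathLike
) -> list[Path]:
    """Write each result table as a TSV with a fixed column order.

    Returns the manifest: the list of files written, in deterministic
    (sorted-by-name) order.  Identical inputs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not os.access(out, os.W_OK):
        raise ValidationError(f"output directory {out} is not writable")
    manifest: list[Path] = []
    for name in sorted(results):
        path = out / f"{name}.tsv"
        results[name].to_csv(path, sep="\t", index=False, lineterminator="\n")
        manifest.append(path)
    return manifest
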