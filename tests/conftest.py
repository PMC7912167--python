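"""Shared fixtures: small programmatically generated inputs."""

from __future__ import annotations

import textwrap

import numpy as np
import pandas as pd
import pytest

from heterodiff.core_io import (
    AlleleCountTable,
    GeneCountMatrix,
    SampleSheet,
    TrioDesign,
)

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##INFO=<ID=QD,Number=1,Type=Float,Description="qual by depth">
    ##INFO=<ID=HRun,Number=1,Type=Integer,Description="homopolymer run">
    ##INFO=<ID=MQ0,Number=1,Type=Integer,Description="mapq0 reads">
    ##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="genotype">
    ##contig=<ID=chr1>
    ##contig=<ID=chr2>
    """
)


def make_vcf(path, records, samples=("FP1", "MP1", "HY1")):
    """Write a minimal plain-text VCF.

    ``records`` are (chrom, pos, ref, alt, qual, info_str, genotypes)
    tuples, genotypes being one GT string per sample.
    """
    lines = [VCF_HEADER.rstrip()]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for chrom, pos, ref, alt, qual, info, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t{info}\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def trio():
    return TrioDesign("HY1", "FP1", "MP1")


@pytest.fixture
def sheet(trio):
    rows = []
    for line, role in (
        ("FP1", "female_parent"),
        ("MP1", "male_parent"),
        ("HY1", "hybrid"),
    ):
        for rep in (1, 2, 3):
            rows.append(
                {
                    "sample_id": f"{line}_r{rep}",
                    "line_id": line,
                    "role": role,
                    "replicate": rep,
                }
            )
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def small_counts(sheet):
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(5)]
    data = {s: rng.integers(10, 1000, size=5) for s in sheet.sample_ids}
    return GeneCountMatrix(pd.DataFrame(data, index=pd.Index(genes, name="gene_id")))


@pytest.fixture
def allele_table():
    rows = [
        # gene gA: two sites, well covered in the hybrid
        ("gA", "chr1", 100, "HY1_r1", 30, 10),
        ("gA", "chr1", 100, "HY1_r2", 25, 12),
        ("gA", "chr1", 150, "HY1_r1", 10, 10),
        ("gA", "chr1", 100, "FP1_r1", 40, 0),
        ("gA", "chr1", 150, "FP1_r1", 35, 0),
        ("gA", "chr1", 100, "MP1_r1", 0, 22),
        ("gA", "chr1", 150, "MP1_r1", 0, 28),
        # gene gB: single site below the coverage threshold
        ("gB", "chr1", 500, "HY1_r1", 6, 3),
        ("gB", "chr1", 500, "FP1_r1", 12, 0),
        ("gB", "chr1", 500, "MP1_r1", 0, 15),
    ]
    return AlleleCountTable(pd.DataFrame(rows, columns=AlleleCountTable.COLUMNS))
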