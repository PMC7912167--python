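"""Synthetic F1-trio transcriptome generator with known regulatory truth.

One trio is two inbred parents (FP female, MP male) and their hybrid,
each with ``replicates`` RNA-seq libraries.  Per gene, a baseline log2
level ``mu`` and cis/trans components ``c`` and ``t`` (log2 units) set
the generative means:

* parents:        ``E[MP] = 2^mu``, ``E[FP] = 2^(mu + c + t)``
* hybrid alleles: ``E[MP_HY] = 2^mu / 2``, ``E[FP_HY] = 2^(mu + c) / 2``
* hybrid total:   ``E[HY] = E[FP_HY] + E[MP_HY]``

The hybrid allelic ratio therefore reflects the cis component only — the
two alleles share one trans environment — while the parental ratio
reflects cis + trans, which is exactly the contrast the downstream
cis/trans classifier exploits.  The hybrid total is the plain sum of the
allelic means (no hybrid-specific global effect), so each gene's
expected inheritance category is derived from the means rather than
drawn.

Counts are negative-binomial with a single experiment-wide dispersion
``alpha`` (variance ``m + alpha * m**2``) and per-sample library size
factors.  Hybrid reads at each diagnostic SNP are split binomially with
maternal probability ``E[FP_HY] / (E[FP_HY] + E[MP_HY])``; parental
reads at the same sites are all-maternal (FP library) or all-paternal
(MP library).  The number of diagnostic SNPs per gene is shifted-Poisson
(minimum 1) and sites are exchangeable.

A fixed seed makes every output byte-identical between runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    AlleleCountTable,
    GeneCountMatrix,
    SampleSheet,
    TraitTable,
    TrioDesign,
    ValidationError,
)
from .inheritance import classify_inheritance_table

REGULATORY_SCENARIOS = (
    "conserved",
    "cis_only",
    "trans_only",
    "cis_trans_enhancing",
    "cis_trans_compensating",
)

# default scenario mix: mirrors the observed prevalence ranking in F1
# transcriptomes (conservation dominates; cis > trans; compensating
# interactions common, enhancing rare)
DEFAULT_MIX = {
    "conserved": 0.50,
    "cis_only": 0.20,
    "trans_only": 0.14,
    "cis_trans_enhancing": 0.02,
    "cis_trans_compensating": 0.14,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic trio experiment.

    ``mean_depth`` is the expected read count per gene per library; with
    the default 1000 each hybrid allele averages ~500 allele-informative
    reads.  ``effect_range`` is the (low, high) uniform range of |c| and
    |t| in log2 units.  ``nb_dispersion`` is the NB alpha; the default
    0.001 models depth-dominated counting noise (counts nearly Poisson
    around the library mean), the regime the downstream count-based
    proportion tests assume.  Biological replicate dispersions an order
    of magnitude larger are realistic for field-grown material but break
    that sampling model; see the methods documentation.
    """

    n_genes: int = 2000
    replicates: int = 3
    mean_depth: float = 1000.0
    nb_dispersion: float = 0.001
    snps_per_gene: float = 4.0
    category_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    effect_range: tuple[float, float] = (1.5, 3.0)
    baseline_log2_sd: float = 0.5
    library_size_factors: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValidationError("need at least 2 replicates")
        if self.mean_depth <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("mean_depth and nb_dispersion must be positive")
        unknown = sorted(set(self.category_mix) - set(REGULATORY_SCENARIOS))
        if unknown:
            raise ValidationError(f"unknown scenarios: {unknown}")
        total = sum(self.category_mix.values())
        if not np.isclose(total, 1.0):
            raise ValidationError(f"category_mix sums to {total}, expected 1")


@dataclass
class SimResult:
    counts: GeneCountMatrix
    allele_counts: AlleleCountTable
    truth: pd.DataFrame
    sheet: SampleSheet
    trio: TrioDesign


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with variance mean + alpha * mean**2."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _draw_effects(
    rng: np.random.Generator, labels: np.ndarray, effect_range: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = effect_range
    n = len(labels)
    mag_c = rng.uniform(lo, hi, size=n)
    mag_t = rng.uniform(lo, hi, size=n)
    sign_c = rng.choice([-1.0, 1.0], size=n)
    sign_t = rng.choice([-1.0, 1.0], size=n)
    c = np.zeros(n)
    t = np.zeros(n)
    cis_like = np.isin(labels, ["cis_only", "cis_trans_enhancing", "cis_trans_compensating"])
    trans_like = np.isin(labels, ["trans_only", "cis_trans_enhancing", "cis_trans_compensating"])
    c[cis_like] = sign_c[cis_like] * mag_c[cis_like]
    t[trans_like] = sign_t[trans_like] * mag_t[trans_like]
    enh = labels == "cis_trans_enhancing"
    t[enh] = np.sign(c[enh]) * np.abs(t[enh])
    comp = labels == "cis_trans_compensating"
    t[comp] = -np.sign(c[comp]) * np.abs(t[comp])
    return c, t


def _make_sheet(trio: TrioDesign, replicates: int) -> SampleSheet:
    rows = []
    for line, role in (
        (trio.female_line, "female_parent"),
        (trio.male_line, "male_parent"),
        (trio.hybrid_line, "hybrid"),
    ):
        for rep in range(1, replicates + 1):
            rows.append(
                {
                    "sample_id": f"{line}_r{rep}",
                    "line_id": line,
                    "role": role,
                    "replicate": rep,
                }
            )
    return SampleSheet(pd.DataFrame(rows))


def simulate_trio_experiment(config: SimConfig) -> SimResult:
    """Generate counts, allele counts, and ground truth for one trio."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    trio = TrioDesign("HY1", "FP1", "MP1")
    sheet = _make_sheet(trio, config.replicates)
    gene_ids = [f"g{i:05d}" for i in range(n)]

    labels = rng.choice(
        list(config.category_mix),
        size=n,
        p=[config.category_mix[k] for k in config.category_mix],
    )
    c, t = _draw_effects(rng, labels, config.effect_range)
    mu = np.log2(config.mean_depth) + rng.normal(0.0, config.baseline_log2_sd, size=n)

    mean_mp = 2.0**mu
    mean_fp = 2.0 ** (mu + c + t)
    allele_fp = 2.0 ** (mu + c) / 2.0
    allele_mp = 2.0**mu / 2.0
    mean_hy = allele_fp + allele_mp
    p_maternal = allele_fp / (allele_fp + allele_mp)

    sf = dict(config.library_size_factors or {})
    line_means = {trio.female_line: mean_fp, trio.male_line: mean_mp, trio.hybrid_line: mean_hy}
    counts = {}
    for sample in sheet.sample_ids:
        line = sheet.df.set_index("sample_id").loc[sample, "line_id"]
        factor = sf.get(sample, 1.0)
        counts[sample] = _nb_draw(rng, line_means[line] * factor, config.nb_dispersion)
    matrix = GeneCountMatrix(pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id")))

    # diagnostic SNP sites: shifted Poisson per gene, exchangeable sites
    n_sites = 1 + rng.poisson(max(config.snps_per_gene - 1.0, 0.0), size=n)
    sample_info = [
        (r.sample_id, r.role, sf.get(r.sample_id, 1.0))
        for r in sheet.df.itertuples(index=False)
    ]
    allele_rows = []
    for gi, gene in enumerate(gene_ids):
        k = n_sites[gi]
        site_pos = 100 * (gi + 1) + np.arange(k)
        for sample, role, factor in sample_info:
            if role == "hybrid":
                total = _nb_draw(rng, np.array([mean_hy[gi] * factor]), config.nb_dispersion)[0]
                per_site = rng.multinomial(total, np.full(k, 1.0 / k))
                maternal = rng.binomial(per_site, p_maternal[gi])
                paternal = per_site - maternal
            elif role == "female_parent":
                total = _nb_draw(rng, np.array([mean_fp[gi] * factor]), config.nb_dispersion)[0]
                maternal = rng.multinomial(total, np.full(k, 1.0 / k))
                paternal = np.zeros(k, dtype=np.int64)
            else:
                total = _nb_draw(rng, np.array([mean_mp[gi] * factor]), config.nb_dispersion)[0]
                paternal = rng.multinomial(total, np.full(k, 1.0 / k))
                maternal = np.zeros(k, dtype=np.int64)
            for s in range(k):
                allele_rows.append(
                    (gene, "chr1", int(site_pos[s]), sample, int(maternal[s]), int(paternal[s]))
                )
    act = AlleleCountTable(
        pd.DataFrame(allele_rows, columns=AlleleCountTable.COLUMNS)
    )

    # expected inheritance category from the noiseless generative means
    expected = classify_inheritance_table(
        pd.DataFrame(
            {"FP": mean_fp, "MP": mean_mp, "HY": mean_hy},
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )["category"]
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "regulatory_label": labels,
            "cis_component": c,
            "trans_component": t,
            "baseline_log2": mu,
            "expected_inheritance": expected.to_numpy(),
            "n_sites": n_sites,
        }
    )
    return SimResult(matrix, act, truth, sheet, trio)


def simulate_traits(
    trios: list[TrioDesign],
    mph_targets: dict[tuple[str, str], float],
    hph_targets: dict[tuple[str, str], float],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_blocks: int = 3,
    hybrid_mean: float = 100.0,
) -> TraitTable:
    """Build a trait table whose noiseless MPH/HPH equal the given targets.

    Targets are keyed by (hybrid_line, trait).  Line means are derived by
    inverting the heterosis definitions with the hybrid mean fixed at
    ``hybrid_mean``:

    * ``M_MiP = M_HY / (1 + MPH/100)``
    * ``M_HiP = M_HY / (1 + HPH/100)``
    * low parent = ``2 * M_MiP - M_HiP``

    which requires MPH >= HPH (else the implied high parent would fall
    below the mid-parent) and a positive implied low parent.  The female
    line is assigned the high-parent mean.  Gaussian block noise with SD
    ``noise_sd`` (trait units) is added per block.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for trio in trios:
        traits = sorted(
            {tr for (h, tr) in mph_targets if h == trio.hybrid_line}
        )
        for trait in traits:
            mph = mph_targets[(trio.hybrid_line, trait)]
            hph = hph_targets[(trio.hybrid_line, trait)]
            if 1 + mph / 100.0 <= 0 or 1 + hph / 100.0 <= 0:
                raise ValidationError("targets imply non-positive means")
            m_mip = hybrid_mean / (1 + mph / 100.0)
            m_hip = hybrid_mean / (1 + hph / 100.0)
            if m_hip < m_mip:
                raise ValidationError(
                    f"targets for {trio.hybrid_line}/{trait} imply high parent "
                    "below mid-parent (MPH < HPH)"
                )
            low = 2 * m_mip - m_hip
            if low <= 0:
                raise ValidationError(
                    f"targets for {trio.hybrid_line}/{trait} imply a "
                    "non-positive low-parent mean"
                )
            means = {
                trio.female_line: m_hip,
                trio.male_line: low,
                trio.hybrid_line: hybrid_mean,
            }
            for line, mean in means.items():
                for block in range(1, n_blocks + 1):
                    value = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    rows.append(
                        {"line_id": line, "block": block, "trait": trait, "value": value}
                    )
    return TraitTable(pd.DataFrame(rows))
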