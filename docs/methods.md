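# Methods

## The problem

In an F1 trio — a female parent line (FP), a male parent line (MP), and
their hybrid (HY) — the hybrid carries one chromosome set from each
parent inside a single cellular environment. That geometry turns an
RNA-seq experiment into a regulatory dissection instrument: because both
parental alleles of a hybrid gene see the same diffusible (trans-acting)
factors, any expression difference *between the two alleles of the
hybrid* must be encoded on the alleles themselves (cis), while the
expression difference *between the two parents* reflects cis and trans
effects together. `heterodiff` implements the full chain from count
tables and variant calls to cis/trans calls, inheritance-mode calls, and
trait heterosis statistics, plus a generator of synthetic trios with
known truth.

## Models and procedures

### Heterosis statistics (`heterodiff.traits`)

For each trait, line means are averaged over replicate blocks with equal
weight. With `M_MiP = (M_FP + M_MP)/2` and `M_HiP = max(M_FP, M_MP)`:

    MPH (%) = 100 (M_HY − M_MiP) / M_MiP
    HPH (%) = 100 (M_HY − M_HiP) / M_HiP

For positive means MPH ≥ HPH algebraically. Uncertainty is reported as
the SD of MPH/HPH recomputed within each block (blocks present for all
three lines), not a delta-method approximation, so it reflects
block-to-block field variation. No outlier trimming is applied: any
removal of extreme plants is a sampling-stage decision upstream of the
trait table.

`simdata.simulate_traits` inverts these definitions: fixing the hybrid
mean at `hybrid_mean` (default 100, arbitrary trait units),
`M_MiP = M_HY/(1 + MPH/100)` and `M_HiP = M_HY/(1 + HPH/100)`, with the
low parent at `2·M_MiP − M_HiP`. This requires MPH ≥ HPH and a positive
implied low parent; both are validated. The high-parent mean is assigned
to the female line — an arbitrary fixed convention, since MPH and HPH
are symmetric in the parents.

### Variant filtering and consistency (`heterodiff.variants`)

Record-level hard filters (all thresholds as conventionally printed for
RNA-seq hard filtering): drop a record if QUAL < 30, QD < 5.0,
HRun > 5, or (MQ0 ≥ 4 and MQ0/DP > 0.1); additionally drop every SNP
lying in a sliding 10-bp window that contains ≥ 3 SNPs. A record whose
INFO lacks a key *passes* that criterion and is flagged `untested` —
"field absent" is deliberately distinct from "fails threshold".

Parent-diagnostic SNPs are sites where the two parents are homozygous
for different alleles (one hom-ref, one hom-alt); heterozygous or
missing parental calls exclude the site.

Hybrid variants are partitioned by presence of the identical
(chrom, pos, alt) allele in each parent's call set into four mutually
exclusive categories: hybrid-specific, consistent-with-both,
consistent-with-male-only, consistent-with-female-only. Matching
requires the same alt allele, not just the position; zygosity is ignored
(allele identity is the conservative choice). The partition is asserted:
category counts always sum to the hybrid total.
`summarize_category_counts` additionally accepts externally tabulated
counts with a separately stated grand total, computing percentages
against that total without requiring the counts to sum to it.

### Differential expression (`heterodiff.de`)

Size factors are median-of-ratios: over genes with nonzero counts in
every sample, the median of count/geometric-mean. Normalized expression
is count/factor, real-valued, kept strictly separate from the integer
count matrix.

The per-gene test is a Welch two-sample t-test on log2(normalized + 1)
replicate values with BH adjustment, an explicit stand-in for a
negative-binomial exact test. A gene is a DEG iff adjusted p ≤ 0.01 and
|log2 fold change| ≥ 1 (fold change ≥ 2), the conventional cutoffs; the
pseudocount of 1 handles zeros. Fold change and direction are computed
on normalized group means relative to the second group of the
comparison (the hybrid, in parent-vs-hybrid contrasts). Normalization is
per comparison pair by default; a `factors` argument switches to global
normalization. Venn-region counts for up to four DEG sets are exact
per-gene enumerations.

What the stand-in does *not* model: NB dispersion shrinkage across
genes. At the simulated depths the Welch test on log counts recovers
8-fold effects with sensitivity 1.0 and empirical FDR 0 (see
`scripts/acceptance.py`); on shallow or highly dispersed real data a
dedicated NB framework will be more powerful.

### Inheritance classification (`heterodiff.inheritance`)

With pseudocount 1, dF = log2(HY+1) − log2(FP+1),
dM = log2(HY+1) − log2(MP+1), and τ = log2(1.25):

- conserved: |dF| ≤ τ and |dM| ≤ τ
- transgressive up / down (VII/VIII): both deviations > τ with the same
  sign
- maternal dominance (V/VI): |dF| ≤ τ < |dM| (VI if FP > MP, else V)
- paternal dominance (III/IV): |dM| ≤ τ < |dF| (IV if MP > FP, else III)
- additive (I/II): both deviations > τ with opposite signs — the hybrid
  sits strictly between parents while deviating > 1.25-fold from both
  (I if FP > MP, else II)

These nine cells partition the (dF, dM) plane; the acceptance suite
proves the partition against an independently coded oracle on a 50³
grid. Comparisons are on the log scale throughout. Two deliberate
interpretations: (a) additive calls *require* >τ deviation from both
parents — a mid-parent hybrid within τ of a parent is dominant or
conserved instead; (b) a hybrid within τ of both parents is conserved
even when the parents differ by more than τ (the residual ambiguous
cell); such calls carry an `ambiguous_conserved` flag. An exact FP = MP
tie cannot produce a dominance call (it forces dF = dM) and so resolves
to conserved or transgressive.

The pipeline classifies genes that are DEGs in at least one
hybrid-parent comparison of the trio (`all_genes=False` default),
since inheritance mode is only meaningful for genes whose expression
actually diverges; `all_genes=True` classifies everything.

### Allele-specific expression (`heterodiff.ase`)

Sites with summed hybrid coverage (maternal + paternal across hybrid
replicates) below 10 reads are dropped; surviving sites are *summed* per
gene — a coverage-weighted aggregate, chosen over averaging per-site
ratios so that deep sites dominate shallow ones. Relative ASE is
100·FP_HY/(FP_HY+MP_HY). Balance is tested with the two-sided exact
binomial test against p = 0.5 — the one-sample exact equivalent of a
2×2 exact test of the split against equal proportions; the exact 2×2
construction the alternative would use is underdetermined without a
second margin, so the one-sample form is the documented choice.
Maternal-share bins are [0,20), [20,40), [40,60), [60,80), [80,100] —
left-closed, final bin closed.

### Cis/trans classification (`heterodiff.cistrans`)

Per gene, from coverage-filtered allele sums (parental libraries scaled
to the hybrid's exposure by size factors and rounded):

    cis   = log2(FP_HY / MP_HY)
    trans = log2(FP / MP) − log2(FP_HY / MP_HY)

so cis + trans = log2(FP/MP) exactly (0.5-read continuity offset in the
log ratios). Three two-sided tests, each BH-adjusted per family across
all genes of the trio:

- **P**: parental counts against a 1:1 split (this test is required to
  separate conserved from cis-/trans-only even though some descriptions
  leave it implicit);
- **C**: hybrid allelic counts against 1:1;
- **T**: equality of the parental and hybrid-allelic proportions.

Totals below 200 reads use exact tests (binomial; Fisher for T), larger
totals the chi-square two-proportion test — matching the "prop. test"
convention while keeping small-sample validity; the chi-square falls
back to Fisher when a table cell is zero. Categories: conserved (none
significant); cis-only (P∧C, not T); trans-only (P∧T, not C); cis+trans
(C∧T, regardless of P) — enhancing if sign(cis) = sign(trans) else
compensating; every other pattern is reported as *ambiguous* rather than
forced into a named category (`fold_ambiguous=True` folds them for
figure parity). The trans-factor scatter plots
x = log2(2·MP_HY/MP) vs y = log2(2·FP_HY/FP): the factor 2 makes one
hybrid allele comparable to a whole single-parent library, since a
conserved gene splits its hybrid expression evenly between alleles.

### Synthetic trios (`heterodiff.simdata`)

Per gene: baseline log2 level μ ~ Normal(log2(mean_depth),
baseline_log2_sd²); a regulatory scenario drawn from `category_mix`;
cis component c and trans component t with |c|,|t| ~
Uniform(effect_range) and signs constrained by the scenario (equal signs
for enhancing, opposite for compensating, zero as appropriate).
Generative means:

    E[MP] = 2^μ            E[FP]    = 2^(μ+c+t)
    E[MP_HY] = 2^μ / 2     E[FP_HY] = 2^(μ+c) / 2
    E[HY] = E[FP_HY] + E[MP_HY]

The hybrid allelic ratio is 2^c (cis only); the parental ratio is
2^(c+t) (cis + trans); the hybrid total is the plain sum of allelic
means (no hybrid-specific global effect), so each gene's expected
inheritance category is *derived* from the means — e.g. pure-cis genes
land additive, pure-trans genes land dominant, compensating genes (equal
parents, imbalanced alleles) land transgressive — rather than drawn.
Counts are NB with one experiment-wide dispersion α (variance
m + αm²; per-gene dispersion adds realism but no test leverage here),
scaled by per-sample library factors. Diagnostic-SNP count per gene is
shifted Poisson (min 1), sites exchangeable; hybrid reads per site split
binomially with maternal probability E[FP_HY]/(E[FP_HY]+E[MP_HY]);
parental reads at the same sites are single-allele. One seed fixes all
randomness; outputs are byte-identical across runs.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_genes | 2000 | enough genes per scenario for stable recovery fractions at interactive runtimes |
| replicates | 3 | standard bulk RNA-seq trio design |
| mean_depth | 1000 reads/gene | ≈ 500 reads per hybrid allele, where 1.5-log2 effects are decisively separated |
| nb_dispersion | 0.001 | depth-dominated counting noise (see below) |
| snps_per_gene | 4 | typical diagnostic-site density for divergent inbred parents |
| effect_range | (1.5, 3.0) log2 | clearly non-conserved effects, the regime the classifiers are specified to recover |
| category_mix | 0.50/0.20/0.14/0.02/0.14 | conservation dominates; cis > trans; compensating common, enhancing rare — the prevalence ranking repeatedly observed in F1 transcriptomes |

**What the generator emulates, and what it does not.** It emulates the
count-level structure the inference consumes: NB-dispersed library
counts, binomial allelic splits, library-size differences, multi-site
genes. It does *not* emulate read-level effects (mapping bias toward the
reference allele, genotyping error, positional site effects) or
biological replicate overdispersion. The dispersion default deserves
emphasis: the cis/trans machinery tests *pooled counts* with
proportion tests whose sampling model is binomial. Counting noise obeys
that model; biological between-replicate variation does not, and at
pooled depths of thousands of reads even α = 0.005 inflates the
parental-divergence chi-square ~6-fold, flooding an all-conserved null
with false calls. With α = 0.001 the chain is calibrated (null
false-call rate 0.2–3.2% after BH at 0.05, across depths 200–1000).
Passing tests therefore demonstrate the correctness and calibration of
the inference machinery under its own sampling assumptions — they do
not demonstrate robustness to biological overdispersion, which on real
field-grown material (α ≈ 0.05 or more) makes count-based proportion
tests anticonservative for the parental contrast. Analyses of such data
should treat P- and T-test significance near the threshold with caution;
the C test (a within-library binomial split) is immune to this effect.

### Pipeline (`heterodiff.pipeline`, CLI)

`run_pipeline` executes simulate → DE → inheritance → ASE → cis/trans
with stage toggles, writes every table as TSV through a deterministic
writer (sorted file order, fixed column order, `\n` line endings), and
records seed, thresholds and the file list in `manifest.json`. Identical
config + seed gives byte-identical outputs. Default thresholds: fold 2,
FDR 0.01, coverage 10, inheritance fold-deviation 1.25, test alpha 0.05.
Logging goes to stderr; results never mix into logs. The `--threads`
flag is accepted for interface parity; results are independent of it.

## Numerical choices

- Pseudocount 1 before any log2 of normalized expression; 0.5 continuity
  offset inside cis/trans log ratios (keeps the additive identity exact
  while handling zero counts).
- BH: vectorized step-up (`p·n/rank`, reverse cumulative minimum,
  capped at 1); validated against a brute-force implementation.
- Exact-vs-asymptotic switch for proportion tests at 200 reads total.
- Ties: FP = MP resolves toward conserved/transgressive (dominance
  unreachable); bin boundary x.0 goes to the right bin, 100 to the last.
- Degenerate inputs: zero-variance Welch tests give p = 1; zero-total
  genes are excluded from cis/trans tests; zero denominators exclude a
  gene from log-ratio scatters; empty categories are absent rows, not
  zeros.

## Problem sizes

The shipped tests and the acceptance script run 2,000-gene trios, a 50³
classification grid, and 1,000 random BH vectors — sizes at which every
recovery fraction is stable to a few tenths of a percent across seeds
while the whole suite stays interactive.

## Known limitations

- The DE test is a log-scale Welch stand-in, not an NB exact test.
- Proportion tests on pooled allele counts assume counting noise;
  biological overdispersion is not modeled (discussed above).
- No mapping-bias correction or phasing; allele counts are taken as
  given in the input table.
- Trait statistics assume complete blocks for SD propagation (means are
  computed regardless; SDs are NaN with < 2 complete blocks).
- The simulator generates one trio per call; multi-trio designs are
  composed by the caller.
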