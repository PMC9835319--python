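# Methods

`corsivkit` analyses systemic interindividual variation (SIV) in DNA
methylation: genomic regions where average CpG methylation differs between
people but is consistent across tissues within a person, so that methylation
in an accessible tissue (blood, skin) reads out the state of internal
organs. The package implements the full analysis stack — SIV validation,
region-level cis-mQTL mapping with the Simes procedure, haplotype allele-sum
association, methylation–expression surrogate inference, flanking-annotation
enrichment, permutation-based GWAS-SNV enrichment, and Tajima's D — together
with a seeded synthetic-cohort generator that supplies data with the
statistical structure those analyses assume.

## Data model and conventions

- Intervals are 0-based half-open (BED convention) everywhere in memory; VCF
  positions are converted from 1-based at the read boundary. Strand is
  ignored (CpG methylation is symmetric).
- Methylation is a **beta value**: fraction methylated, in [0, 1]. Percent
  appears only in reports. Region methylation is the coverage-weighted mean
  over the region's CpGs, `Σ n_meth / Σ (n_meth + n_unmeth)`, masked missing
  when total depth falls below `min_depth` (default 10). Whether to weight by
  coverage was an open choice; the weighted mean uses all reads and reduces
  to the plain mean at equal depth.
- The **M value** is `log2(β'/(1−β'))` with β clamped to `[ε, 1−ε]`,
  ε = 0.001 by default. The clamp keeps fully (un)methylated regions finite;
  0.001 is well below one read at typical depths.
- Genotypes are **minor-allele counts** g ∈ {0, 1, 2}, with the minor allele
  defined cohort-relatively (sample frequency ≤ 0.5 in the loaded donors,
  ties toward alt). The sign convention "negative slope = major allele
  predicts higher methylation" is only meaningful under cohort-relative
  coding. The VCF writer canonicalises to this coding, so write→read round
  trips are exact.

## Statistical procedures

**SIV screen.** For each region and unordered tissue pair, Pearson
correlation of per-donor methylation over donors observed in both tissues;
pairs with fewer than `min_pair_donors` (default 10) shared donors are
skipped. A region is SIV when every pair is computed and every correlation
exceeds 0.6. Donor clustering treats each (donor, tissue) sample as a vector
over fully observed regions, uses 1 − Pearson r distance with average
linkage (the linkage/distance were an open choice; both are exposed), cuts
the tree at k = n_donors, and scores the adjusted Rand index against donor
identity. Interindividual range is the full min–max span per region and
tissue, in percent.

**cis-mQTL scan.** For every SNV within 1 Mb of either region boundary:
Spearman rank correlation (average ranks for ties, t-approximation p) of
region methylation with g, plus OLS slope `b` and R² of methylation on g.
Significance is rank-based; effect sizes are regression-based — the scan's
p-values are robust to the methylation scale while b stays interpretable as
methylation change per allele copy. SNVs monomorphic in-sample or with fewer
than `min_donors` (default 20) complete pairs are skipped and counted. The
**Simes correction** collapses the per-SNV p-vector: sort ascending, return
`min_i n·p(i)/i` (capped at 1). The **Simes SNV** is the SNV attaining the
minimising term; ties break deterministically by smallest raw p, then
distance to the region, then genomic position. Benjamini–Hochberg FDR is
applied across regions within each tissue (significance at q < 0.05).

**Effect aggregation.** `delta = 2|b|` is the fitted methylation difference
between the two homozygote classes; `delta × R²` is the absolute methylation
variation explained by genotype. Aggregation restricts to associations with
raw p < 1e-10 (a conservative multiplicity guard) and reports median and sum
of delta × R², median R², and the fraction of negative slopes. Dividing the
median delta × R² by the median R² recovers the implied interindividual
range for a region of typical effect strength. In M-mode the OLS is re-run
on M-transformed methylation (b then in M units); the rank-based p-values
are unchanged by the monotone transform, so the two modes always agree on
the sign of b.

**Haplotype allele sum.** The haplotype block overlapping each region
(largest overlap, then most SNVs, then leftmost) supplies a per-donor sum of
minor alleles across its SNVs; Pearson r and an OLS fit against region
methylation give the block-level effect. Donors missing any block genotype
are excluded rather than imputed (imputation is out of scope); blocks are
inputs, not inferred.

**Methylation–expression.** Spearman correlation per region–gene pair in a
target tissue, BH FDR within the tissue (Spearman because expression units
are whatever the input provides; only a median-level filter is applied).
Surrogate recovery recomputes the correlation using the surrogate tissue's
methylation against the *target* tissue's expression; a pair is recovered at
nominal p < 0.05 with the same sign — nominal rather than FDR because the
set was already selected in the target tissue. The positional odds ratio
tabulates (within 3 kb of a gene end vs gene body) × (negative vs positive
correlation), with a Haldane 0.5 correction on zero cells (flagged) and a
two-sided Fisher exact p.

**Flanking enrichment.** Controls are matched per query region on
chromosome, length (±10%) and CpG density (±20%, both relative) without
replacement; the tolerances are a feasibility choice at desk scale and are
logged. At each offset d ∈ 1..50 kb, the two 1-kb windows
`[start−d·1000, start−(d−1)·1000)` and `[end+(d−1)·1000, end+d·1000)`
(two-sided, excluding the region body) define a hit when ≥1 element of a
class overlaps either; each class × offset cell gets a two-sided Fisher
exact test and the profile is BH-adjusted across all cells.

**GWAS permutation.** Observed overlap (by chrom+pos, avoiding rsID version
drift) of the pooled mQTL SNVs with a catalog category; each of B (default
1000) permutations redraws, per region, the same number of SNVs uniformly
without replacement from the cohort SNVs within 1 Mb of that region. The
per-region overlap count under this scheme is exactly hypergeometric, so the
null is sampled as a sum of independent hypergeometric draws — identical in
distribution to drawing the SNVs, at a fraction of the cost.
`p_perm = (1 + #{null ≥ obs})/(B + 1)`, Bonferroni across categories.
Because overlap counts are discrete, p_perm is exactly uniform only at
attainable values and conservative between them; calibration checks need
enough regions/SNVs for a fine-grained null.

**eQTL bootstrap.** Proportion of query SNVs in an eQTL lookup versus B
bootstrap samples of equal size from a background set; fold = observed /
mean(null) with a 2.5–97.5 percentile interval.

**Tajima's D.** Over biallelic sites inside a region with n = 2 × donors
chromosomes: S polymorphic sites, π = Σ 2k(n−k)/(n(n−1)) from minor-allele
counts k, and D = (π − S/a₁)/√(e₁S + e₂S(S−1)) with the standard constants
a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ as functions of n. D is missing when S = 0;
complete genotypes are required so a single n applies to all sites. The
implementation is verified against a brute-force pairwise-difference oracle
to 1e-12.

## The synthetic cohort

The generator emulates the structure the analyses assume; its defaults are
the study conditions under which the test suite runs.

| parameter | default | meaning |
|---|---|---|
| `n_donors` / `n_regions` / `n_tissues` | 500 / 100 / 6 | cohort dimensions |
| `snvs_per_region_window` (+`snvs_in_region`) | 40 (+2) | SNVs per cis window / inside the region |
| `window_bp` | 1,000,000 | cis window |
| `maf_range` | (0.1, 0.5) | minor-allele frequencies |
| `p_negative_beta` | 0.8 | share of negative causal slopes |
| `beta_magnitude_range` | (0.05, 0.25) | causal slope magnitude (fraction/allele) |
| `sigma_donor` / `sigma_tissue` | 0.04 / 0.03 | systemic donor effect vs tissue noise (sd) |
| `ld_block_size` / `ld_r` | 5 / 0.9 | block size / adjacent-SNV allele correlation |
| `expr_coupling` / `expr_noise_sd` | 3.0 / 0.3 | expression slope on methylation / noise |
| `repeat_lambda0`, `repeat_amplitude`, `repeat_decay_bp` | 0.15, 6 (LINE1/LTR), 5000 | flank element intensity and decay |

Methylation is `clamp01(μ_r + b_r·g + u_donor + ε_donor,tissue)`: one causal
SNV per region (the one nearest the region), a donor effect `u` shared
across tissues — this *is* the systemic component — and independent tissue
noise. μ_r centres the expectation at 0.5 so the [0,1] clamp is rarely hit
(the clamped fraction is reported; <1% under defaults). The truth table
records the causal SNV, b, and the analytic
R² = Var(b·g)/(Var(b·g) + σ_d² + σ_t²) with Var(g) = 2p(1−p). A hard clamp
rather than a logistic link keeps b interpretable on the beta scale. The
noise scales were chosen so the typical single-SNV R² is high (≈0.75),
matching the regime of strong genetic control the analyses target.

Design choices worth noting:

- **Exact sign share.** Exactly `round(p_negative_beta · n_regions)` regions
  get a negative slope (seeded assignment) instead of i.i.d. sign draws: the
  sign skew is a condition of the study, not a sampling variable, and
  recovery checks then test the pipeline rather than binomial noise.
- **Blocks never straddle a region.** LD-block boundaries are cut at each
  region's edges, so the SNVs inside a region share one block and the block
  overlapping a region always carries its causal SNV — identifiable truth
  for the haplotype analysis. Within a block, haplotypes follow a copy chain
  (allele j+1 copies allele j with probability `ld_r`, else is redrawn at
  the block frequency), giving adjacent-SNV allele correlation `ld_r` with
  the correct marginal frequency.
- **Single causal SNV per region.** Real data show many associated SNVs per
  region through LD; here the block structure induces that multiplicity
  qualitatively while keeping the truth identifiable.
- Expression is linear in methylation with a per-gene sign; regions near a
  gene end receive a negative sign with probability 0.8, planting the
  positional bias the odds-ratio analysis recovers.
- Annotation elements are Poisson in 1-kb flank bins with intensity
  `λ0·(1 + A·exp(−d/decay))` around query regions and flat `λ0` around
  controls.
- GWAS catalogs sample SNVs with weight `fold` on a designated (causal/mQTL)
  set and 1 otherwise, without replacement within a category.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: cell-type composition effects (the regions are
defined as unaffected by them), read-level bisulfite noise and coverage
variation (region values are exact fractions plus Gaussian noise), realistic
LD decay and population structure (blocks are exchangeable and independent),
covariates such as age or ancestry, trans effects, and tissue-specific
confounding. Results on synthetic data demonstrate correctness and
calibration of the procedures, not effect sizes in any real cohort.

## Numerical and degenerate-input policy

Zero-variance vectors (monomorphic SNVs, constant methylation or
expression) are skipped and counted, never silently propagated. Undefined
odds ratios are Haldane-corrected and flagged; undefined correlation
distances (constant sample vectors) are treated as maximal distance. All
tie-breaks (Simes SNV, block selection) are total orders, so every run is
reproducible byte-for-byte given a seed; each consumer of randomness derives
an independent stream from the config seed.

## Problem sizes

The bundled analysis scripts use 300 donors × 80 regions × 6 tissues; the
test suite and the reproduction script use the default 500 × 100 conditions
(scans in one or two tissues) plus targeted perturbations (null calibration
at 200 × 200 with all effects removed; a 150-region geometry for the planted
enrichment fixture; 200 replicate catalogs at B = 1000 for permutation
calibration). These sizes give stable statistics while a full run of suite
plus scripts completes in a few minutes on one CPU.

## Known limitations

Real-data mode expects pre-phased haplotype blocks and pre-computed
annotation tracks as inputs; block discovery, phasing, alignment and QC are
out of scope. The permutation null conditions on the observed per-region SNV
counts; it does not model LD between catalog SNVs. Surrogate recovery is
assessed at nominal significance, so its absolute level depends on the
target-tissue selection step. Tajima's D requires complete genotypes within
a region.
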