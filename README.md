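# corsivkit

Analysis of **systemic interindividual variation (SIV)** in DNA methylation:
genomic regions where average CpG methylation differs between individuals
but is consistent across tissues within an individual, so that blood or skin
methylation can stand in for internal organs. `corsivkit` is for
epigenomics researchers who want a tested, reusable implementation of the
statistics used to characterise such regions: region-level methylation QTL
mapping, haplotype association, surrogate-tissue inference, and
genomic-context enrichment — exercised end-to-end on a seeded synthetic
cohort generator, or on real region/VCF/TSV inputs.

## The statistics at the core

For each region with per-donor average methylation β (a fraction in [0, 1])
and each SNV within 1 Mb carrying minor-allele count g ∈ {0, 1, 2}, the scan
computes a Spearman rank p-value and an OLS fit β = μ + b·g + ε. The
**Simes procedure** collapses the n per-SNV p-values to one region-level
adjusted p,

    p_Simes = min_i  n · p(i) / i    (p(1) ≤ … ≤ p(n)),

naming the minimising SNV the **Simes SNV**; Benjamini–Hochberg FDR is then
applied across regions within each tissue. Effect sizes are summarised by
Δ = 2|b| (the fitted span between homozygote classes) and Δ·R², the absolute
methylation variation explained by genotype. A negative b means the major
allele predicts higher methylation. Complementary modules cover inter-tissue
Pearson correlation screens with donor clustering, haplotype allele-sum
regression, Spearman methylation–expression association with
surrogate-tissue recovery and a positional sign odds ratio, Fisher-exact
sliding-window annotation enrichment against matched controls, permutation
GWAS-SNV overlap tests, bootstrap eQTL enrichment, and Tajima's D. See
`docs/methods.md` for the full model and parameter description.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (300 donors, 80 regions, 6 tissues, seed 17). `01_simulate.py` writes
the fixture files (BED, VCF, TSV) under `results/fixtures/`; each later
script reads them back and prints what it finds:

```sh
cd analysis
python 01_simulate.py
python 02_siv_screen.py
python 03_mqtl_scan.py
```

`02_siv_screen.py` prints:

```
SIV confirmed (all pairs R > 0.6) for 100% of regions
median minimum pair correlation: 0.892
donor-clustering adjusted Rand index: 1.000 (1.0 = samples group perfectly by donor)
median interindividual range in blood: 50.8% methylation
```

— every region's methylation correlates across all 15 tissue pairs, and
(donor, tissue) samples cluster perfectly by donor: the variation is
systemic, an epigenetic polymorphism of the individual. `03_mqtl_scan.py`
prints:

```
blood: 80/80 regions significant at FDR < 0.05
associations with raw p < 1e-10: 160
  median R^2 = 0.74
  fraction negative slopes = 0.78
  median delta x R^2 = 21.6% methylation
  implied interindividual range = 29.0% methylation
Simes SNVs within 10 kb of their region: 100%
slope recovery vs truth (blood): median |error| = 0.0033
```

— genetic control is strong (a typical SNV explains ~74% of the methylation
variance), slopes are skewed negative (the major allele predicts higher
methylation), and the fitted slopes match the generator's truth table to
three decimals. Scripts `04`–`07` continue with the haplotype allele-sum
analysis, surrogate-tissue recovery (100% of thyroid associations recovered
from blood methylation; positional OR 4.48, Fisher p = 0.0026), LINE1/LTR
flank enrichment, GWAS category enrichment (all categories enriched except
cancer), a 3.2-fold eQTL enrichment of Simes SNVs, and higher Tajima's D in
query regions than matched controls.

The same stages are available as a CLI over a YAML config
(`corsivkit run --config cfg.yaml --outdir out --seed 1`), with subcommands
`simulate siv mqtl haplo methexpr enrich gwasperm tajima`.

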