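"""Generate the synthetic study cohort and write every fixture file.

Conditions: 300 donors, 80 regions, 6 tissues; one causal cis SNV per
region with 80% negative slopes; systemic donor effect (sd 0.04) above the
per-tissue noise (sd 0.03); LD blocks of 5 SNVs at r = 0.9; expression
coupled to methylation; repeats with 5-kb distance decay around the query
regions; GWAS catalogs in which every category except cancer oversamples
the causal SNVs 6-fold.
"""

from __future__ import annotations

from common import FIXTURES, STUDY

from corsivkit import io
from corsivkit.simulate import (
    GWAS_CATEGORIES,
    simulate_annotations,
    simulate_expression,
    simulate_genotypes,
    simulate_gwas_catalog,
    simulate_methylation,
    simulate_regions,
)


def main() -> None:
    cfg = STUDY
    FIXTURES.mkdir(parents=True, exist_ok=True)
    regions, pool, cpgs = simulate_regions(cfg)
    gset, blocks = simulate_genotypes(cfg, regions)
    msim = simulate_methylation(cfg, gset, regions)
    esim = simulate_expression(cfg, msim.meth, regions)
    track = simulate_annotations(cfg, regions, pool)
    folds = {c: (1.0 if c == "cancer" else 6.0) for c in GWAS_CATEGORIES}
    catalog = simulate_gwas_catalog(cfg, gset, msim.truth["causal_snv_id"],
                                    folds, category_size=400)

    io.write_regions(regions, FIXTURES / "regions.bed")
    io.write_regions(pool, FIXTURES / "control_pool.bed")
    io.write_genotypes(gset, FIXTURES / "genotypes.vcf")
    io.write_haplotype_blocks(blocks, FIXTURES / "blocks.bed")
    io.write_methylation(msim.meth, FIXTURES / "methylation.tsv")
    io.write_expression(esim.expr, FIXTURES / "expression.tsv")
    io.write_annotations(track, FIXTURES / "annotations.bed")
    io.write_gwas_catalog(catalog, FIXTURES / "gwas_catalog.tsv")
    msim.truth.to_csv(FIXTURES / "truth_methylation.tsv", sep="\t", index=False)
    esim.truth.to_csv(FIXTURES / "truth_expression.tsv", sep="\t", index=False)

    print(f"wrote fixtures to {FIXTURES}")
    print(f"  {len(regions)} regions, {len(gset)} SNVs in {len(blocks)} blocks, "
          f"{cfg.n_donors} donors x {cfg.n_tissues} tissues")
    print(f"  clamped methylation cells: {msim.clamped_fraction:.2%}")


if __name__ == "__main__":
    main()
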