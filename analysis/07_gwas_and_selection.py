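"""GWAS-SNV permutation enrichment, eQTL bootstrap, Tajima's D.

mQTL SNVs (Simes SNVs from the blood scan) are tested for overlap with each
GWAS catalog category against a null that redraws, per region, the same
number of SNVs from the region's cis window. A bootstrap quantifies how
much more often Simes SNVs appear in a (synthetic) eQTL lookup than random
background SNVs, and Tajima's D is compared between region sets with
intermediate-frequency vs rare site spectra.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from common import RESULTS, STUDY, load_fixtures

from corsivkit import enrichment, mqtl
from corsivkit.simulate import simulate_region_sites


def main() -> None:
    fx = load_fixtures()
    rec = mqtl.fdr_across_regions(
        mqtl.scan_regions(fx["meth"], fx["genotypes"], fx["regions"], "blood"))
    sig = rec[rec["significant"] & rec["simes_snv_id"].notna()]
    mqtl_snvs = {rid: sorted(set(g["simes_snv_id"]))
                 for rid, g in sig.groupby("region_id")}
    print(f"{len(mqtl_snvs)} regions contribute mQTL SNVs")

    results = enrichment.gwas_permutation(mqtl_snvs, fx["catalog"],
                                          fx["genotypes"], fx["regions"],
                                          B=1000, seed=STUDY.seed)
    rows = [{"category": r.category, "observed": r.observed_overlap,
             "null_mean": float(r.null_overlaps.mean()), "fold": r.fold,
             "p_perm": r.p_perm, "p_bonferroni": r.p_bonferroni}
            for r in results]
    df = pd.DataFrame(rows).sort_values("fold", ascending=False)
    df.to_csv(RESULTS / "gwas_permutation.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    enriched = df[df["p_bonferroni"] < 0.05]["category"].tolist()
    print(f"enriched categories (Bonferroni < 0.05): {enriched}")

    # synthetic eQTL lookup: half the background, Simes SNVs oversampled
    rng = np.random.default_rng(STUDY.seed)
    background = fx["genotypes"].snv_ids
    simes = sorted({s for ids in mqtl_snvs.values() for s in ids})
    in_lookup = {s for s in background
                 if rng.random() < (0.85 if s in simes else 0.25)}
    boot = enrichment.eqtl_bootstrap(simes, in_lookup, background, B=1000,
                                     seed=STUDY.seed)
    print(f"eQTL enrichment of Simes SNVs: {boot.fold:.2f}-fold "
          f"[{boot.ci_low:.2f}, {boot.ci_high:.2f}]")

    controls = enrichment.matched_controls(fx["regions"], fx["pool"],
                                           seed=STUDY.seed)
    sets = {}
    for name, rset, maf_range in (("query", fx["regions"], (0.2, 0.5)),
                                  ("control", controls, (0.02, 0.2))):
        sites = simulate_region_sites(rset, 8, maf_range, STUDY.n_donors,
                                      seed=STUDY.seed)
        scan = enrichment.tajimas_d_scan(sites, rset)
        scan.to_csv(RESULTS / f"tajima_{name}.tsv", sep="\t", index=False)
        sets[name] = scan["D"].dropna()
        print(f"median Tajima's D ({name}): {sets[name].median():.2f}")
    comp = enrichment.compare_region_sets(sets)
    comp.to_csv(RESULTS / "tajima_comparison.tsv", sep="\t", index=False)
    print(f"rank-sum p (query vs control): {comp['p'].iloc[0]:.3g}")


if __name__ == "__main__":
    main()
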