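"""Shared setup for the numbered analysis scripts.

Every script works from the same on-disk fixture set under
``results/fixtures`` (created by ``01_simulate.py``), so each stage reads
the exchange formats the pipeline defines rather than in-memory objects.
"""

from __future__ import annotations

from pathlib import Path

from corsivkit import io
from corsivkit.simulate import GWAS_CATEGORIES, SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
FIXTURES = RESULTS / "fixtures"

#: study conditions for the worked analysis (seeded; rerun 01 to regenerate)
STUDY = SimulationConfig(n_donors=300, n_regions=80, n_tissues=6, seed=17)


def require_fixtures() -> None:
    if not (FIXTURES / "regions.bed").exists():
        raise SystemExit("fixtures missing - run analysis/01_simulate.py first")


def load_fixtures() -> dict:
    require_fixtures()
    import pandas as pd

    return {
        "regions": io.read_regions(FIXTURES / "regions.bed", name="query"),
        "pool": io.read_regions(FIXTURES / "control_pool.bed",
                                name="control_pool"),
        "genotypes": io.read_genotypes(FIXTURES / "genotypes.vcf"),
        "blocks": io.read_haplotype_blocks(FIXTURES / "blocks.bed"),
        "meth": io.read_methylation(FIXTURES / "methylation.tsv"),
        "expr": io.read_expression(FIXTURES / "expression.tsv"),
        "annotations": io.read_annotations(FIXTURES / "annotations.bed"),
        "catalog": io.read_gwas_catalog(FIXTURES / "gwas_catalog.tsv",
                                        GWAS_CATEGORIES),
        "truth": pd.read_csv(FIXTURES / "truth_methylation.tsv", sep="\t"),
    }
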