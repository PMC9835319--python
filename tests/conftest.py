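"""Shared synthetic cohorts, generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from corsivkit import mqtl
from corsivkit.simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_genotypes,
    simulate_methylation,
    simulate_regions,
)


class Cohort:
    """Bundle of the simulated objects downstream stages consume."""

    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.regions, self.pool, self.cpg_positions = simulate_regions(cfg)
        self.genotypes, self.blocks = simulate_genotypes(cfg, self.regions)
        sim = simulate_methylation(cfg, self.genotypes, self.regions)
        self.meth = sim.meth
        self.truth = sim.truth
        self.clamped_fraction = sim.clamped_fraction
        esim = simulate_expression(cfg, self.meth, self.regions)
        self.expr = esim.expr
        self.expr_truth = esim.truth

    @property
    def pairs(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"region_id": r.region_id, "gene_id": r.gene_id}
             for r in self.regions if r.gene_id]
        )


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """120 donors, 20 regions, 3 tissues: quick but statistically usable."""
    return Cohort(
        SimulationConfig(
            n_donors=120, n_regions=20, n_tissues=3,
            snvs_per_region_window=12, seed=101,
        )
    )


@pytest.fixture(scope="session")
def recovery_cohort() -> Cohort:
    """The default study conditions (500 donors, 100 regions)."""
    return Cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def recovery_records(recovery_cohort) -> pd.DataFrame:
    rec = mqtl.scan_regions(
        recovery_cohort.meth, recovery_cohort.genotypes,
        recovery_cohort.regions, "blood",
    )
    return mqtl.fdr_across_regions(rec)
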