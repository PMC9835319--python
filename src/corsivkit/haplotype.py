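"""Haplotype-level mQTL: allele-sum association per region.

A coarser complement to the single-SNV scan: for the haplotype block
overlapping each region, each donor's minor alleles are summed over the
block's SNVs and the sum is correlated with region methylation. Blocks are
inputs (from external phasing); donors missing any block genotype are
excluded rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .types import GenotypeSet, HaplotypeBlock, HaplotypeBlockSet, Region, RegionSet

logger = logging.getLogger(__name__)


def block_for_region(
    region: Region, blocks: HaplotypeBlockSet
) -> Optional[HaplotypeBlock]:
    """The block overlapping the region.

    Several overlapping blocks resolve to the largest overlap, then the most
    SNVs, then the leftmost start. Returns None (logged) when no block
    overlaps.
    """
    candidates = [b for b in blocks if b.overlap_bp(region) > 0]
    if not candidates:
        logger.info("region %s overlaps no haplotype block; skipped", region.region_id)
        return None
    return max(
        candidates,
        key=lambda b: (b.overlap_bp(region), len(b.snv_ids), -b.start),
    )


def allele_sum(
    gset: GenotypeSet, block: HaplotypeBlock
) -> tuple[np.ndarray, int]:
    """Per-donor sum of minor alleles over the block SNVs.

    Donors missing any block SNV get NaN; the count of excluded donors is
    returned alongside.
    """
    if not block.snv_ids:
        raise ValueError(f"block {block.block_id} contains no SNVs")
    idx = [gset.index_of(s) for s in block.snv_ids]
    g = gset.g[idx]  # (n_block_snvs, n_donors)
    sums = g.sum(axis=0)
    excluded = int(np.isnan(sums).sum())
    return sums, excluded


@dataclass
class HaplotypeAssociation:
    region_id: str
    block_id: str
    r: float
    b_h: float
    r2_h: float
    n_donors: int
    n_excluded: int


def haplotype_association(
    region_id: str,
    block: HaplotypeBlock,
    region_meth: np.ndarray,
    meth_mask: np.ndarray,
    allele_sums: np.ndarray,
    min_donors: int = 20,
) -> Optional[HaplotypeAssociation]:
    """Pearson correlation and OLS fit of methylation on the allele sum.

    Returns None (flagged in the log) when too few donors remain or the
    allele sum has zero variance.
    """
    valid = meth_mask & ~np.isnan(allele_sums)
    n = int(valid.sum())
    excluded = int(len(allele_sums) - n)
    if n < min_donors:
        logger.info("region %s: %d donors < min_donors; association missing",
                    region_id, n)
        return None
    a, y = allele_sums[valid], region_meth[valid]
    if a.std() == 0 or y.std() == 0:
        logger.info("region %s: zero variance; association missing", region_id)
        return None
    r = float(pearsonr(a, y).statistic)
    b_h = float(np.cov(a, y, ddof=1)[0, 1] / np.var(a, ddof=1))
    return HaplotypeAssociation(region_id, block.block_id, r, b_h, r * r, n, excluded)


def haplotype_scan(
    meth,
    gset: GenotypeSet,
    regions: RegionSet,
    blocks: HaplotypeBlockSet,
    tissue: str,
    min_donors: int = 20,
) -> pd.DataFrame:
    """Allele-sum association for every region in one tissue."""
    k = meth.tissue_index(tissue)
    rows = []
    for region in regions:
        block = block_for_region(region, blocks)
        if block is None:
            continue
        sums, _ = allele_sum(gset, block)
        i = meth.region_index(region.region_id)
        assoc = haplotype_association(
            region.region_id, block, meth.values[i, :, k], meth.mask[i, :, k],
            sums, min_donors,
        )
        if assoc is not None:
            rows.append(assoc.__dict__)
    return pd.DataFrame(
        rows,
        columns=["region_id", "block_id", "r", "b_h", "r2_h", "n_donors",
                 "n_excluded"],
    )
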