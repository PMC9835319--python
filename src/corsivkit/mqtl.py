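"""Region-level cis-mQTL mapping with the Simes procedure.

Per region and tissue, every SNV within the cis window is tested with a
Spearman rank correlation against average region methylation; the Simes
correction collapses the per-SNV p-values into a single region-level
adjusted p and names the most strongly associated SNV (the Simes SNV).
Benjamini-Hochberg FDR is then applied across regions within each tissue.
Effect sizes (slope b, R^2) come from ordinary least squares of methylation
on the 0/1/2 minor-allele count; significance comes from the rank test.

The genotype-associated methylation span is delta = 2|b| (the fitted
difference between the two homozygote classes) and delta * R^2 measures the
absolute methylation variation explained by genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import m_transform
from .types import GenotypeSet, HaplotypeBlockSet, Region, RegionSet

RECORD_COLUMNS = [
    "region_id", "tissue", "simes_snv_id", "simes_p_adjusted", "b", "r2",
    "delta", "delta_x_r2", "snv_distance", "n_snvs_tested",
    "n_snvs_below_1e10", "simes_snv_raw_p",
]


def spearman_scan(
    y: np.ndarray,
    y_mask: np.ndarray,
    gset: GenotypeSet,
    region: Region,
    cis_window: int = 1_000_000,
    min_donors: int = 20,
) -> pd.DataFrame:
    """Per-SNV association of one region's methylation with cis genotypes.

    Returns one row per testable SNV within ``cis_window`` of either region
    boundary: Spearman rho (average ranks for ties) and its t-approximation
    p-value, plus OLS slope ``b`` and coefficient of determination ``r2`` of
    methylation on minor-allele count. SNVs monomorphic among the analysed
    donors, or with fewer than ``min_donors`` complete pairs, are skipped.
    """
    rows = []
    for i, snv in enumerate(gset.snvs):
        if snv.chrom != region.chrom:
            continue
        dist = region.distance_to(snv.pos0)
        if dist > cis_window:
            continue
        g = gset.g[i]
        valid = y_mask & ~np.isnan(g)
        n = int(valid.sum())
        if n < min_donors:
            rows.append((snv.snv_id, snv.pos, dist, n, np.nan, np.nan,
                         np.nan, np.nan, "too_few_donors"))
            continue
        gv, yv = g[valid], y[valid]
        if gv.std() == 0:
            rows.append((snv.snv_id, snv.pos, dist, n, np.nan, np.nan,
                         np.nan, np.nan, "monomorphic"))
            continue
        if yv.std() == 0:
            rows.append((snv.snv_id, snv.pos, dist, n, np.nan, np.nan,
                         np.nan, np.nan, "constant_methylation"))
            continue
        res = stats.spearmanr(gv, yv)
        rho, p = float(res.statistic), float(res.pvalue)
        b = float(np.cov(gv, yv, ddof=1)[0, 1] / np.var(gv, ddof=1))
        r = float(np.corrcoef(gv, yv)[0, 1])
        rows.append((snv.snv_id, snv.pos, dist, n, rho, p, b, r * r, "ok"))
    return pd.DataFrame(
        rows,
        columns=["snv_id", "pos", "distance", "n", "rho", "p", "b", "r2", "status"],
    )


def simes_correct(raw_p: Sequence[float]) -> float:
    """Simes-adjusted p-value: min over i of n * p_(i) / i, capped at 1."""
    p = np.asarray(list(raw_p), dtype=float)
    if p.size == 0:
        raise ValueError("simes_correct requires at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.sort(p)
    terms = n * order / np.arange(1, n + 1)
    return float(min(terms.min(), 1.0))


def simes_snv(scan: pd.DataFrame) -> tuple[float, pd.Series]:
    """Simes-adjusted p and the SNV attaining the minimising term.

    Ties on the minimising term break by smallest raw p, then smallest
    distance to the region, then lowest genomic position, so the selection
    is fully deterministic.
    """
    ok = scan[scan["status"] == "ok"].copy()
    if ok.empty:
        raise ValueError("no testable SNV in scan")
    n = len(ok)
    ok = ok.sort_values("p", kind="mergesort").reset_index(drop=True)
    ok["simes_term"] = n * ok["p"].to_numpy() / np.arange(1, n + 1)
    p_adj = float(min(ok["simes_term"].min(), 1.0))
    best = ok[ok["simes_term"] == ok["simes_term"].min()]
    best = best.sort_values(["p", "distance", "pos"], kind="mergesort")
    return p_adj, best.iloc[0]


def scan_regions(
    meth,
    gset: GenotypeSet,
    regions: RegionSet,
    tissue: str,
    cis_window: int = 1_000_000,
    min_donors: int = 20,
    scale: str = "beta",
    p_multiplicity_threshold: float = 1e-10,
    keep_scans: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Run the cis scan for every region in one tissue.

    ``scale='M'`` re-runs the OLS on M-transformed methylation (slope and
    delta then in M units per allele copy); the rank-based significance is
    unchanged by the monotone transform. Returns one record per region (FDR
    q added by :func:`fdr_across_regions`); ``keep_scans`` additionally
    returns the per-SNV scan tables keyed by region_id.
    """
    if scale not in ("beta", "M"):
        raise ValueError("scale must be 'beta' or 'M'")
    k = meth.tissue_index(tissue)
    records, scans = [], {}
    for region in regions:
        i = meth.region_index(region.region_id)
        y = meth.values[i, :, k]
        if scale == "M":
            y = m_transform(y)
        ymask = meth.mask[i, :, k]
        scan = spearman_scan(y, ymask, gset, region, cis_window, min_donors)
        if keep_scans:
            scans[region.region_id] = scan
        ok = scan[scan["status"] == "ok"]
        if ok.empty:
            records.append(
                dict(zip(RECORD_COLUMNS,
                         [region.region_id, tissue, None, np.nan, np.nan, np.nan,
                          np.nan, np.nan, np.nan, 0, 0, np.nan]))
            )
            continue
        p_adj, best = simes_snv(scan)
        delta = 2.0 * abs(best["b"])
        records.append(
            {
                "region_id": region.region_id,
                "tissue": tissue,
                "simes_snv_id": best["snv_id"],
                "simes_p_adjusted": p_adj,
                "b": best["b"],
                "r2": best["r2"],
                "delta": delta,
                "delta_x_r2": delta * best["r2"],
                "snv_distance": int(best["distance"]),
                "n_snvs_tested": len(ok),
                "n_snvs_below_1e10": int((ok["p"] < p_multiplicity_threshold).sum()),
                "simes_snv_raw_p": best["p"],
            }
        )
    out = pd.DataFrame(records, columns=RECORD_COLUMNS)
    return (out, scans) if keep_scans else out


def fdr_across_regions(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg across regions (within one tissue).

    Adds ``fdr_q`` and ``significant`` columns; regions with no testable SNV
    keep a missing q and are never significant.
    """
    if records.empty:
        raise ValueError("no regions to correct")
    out = records.copy()
    out["fdr_q"] = np.nan
    out["significant"] = False
    tested = out["simes_p_adjusted"].notna()
    if tested.any():
        _, q, _, _ = multipletests(out.loc[tested, "simes_p_adjusted"],
                                   alpha=alpha, method="fdr_bh")
        out.loc[tested, "fdr_q"] = q
        out.loc[tested, "significant"] = q < alpha
    return out


@dataclass
class EffectSummary:
    median_delta_x_r2: float
    sum_delta_x_r2: float
    median_r2: float
    fraction_b_negative: float
    n_records: int


def effect_aggregation(
    records: pd.DataFrame, p_threshold: float = 1e-10
) -> EffectSummary:
    """Aggregate effect sizes over records passing the raw-p threshold.

    The conservative threshold (default 1e-10 on the Simes SNV's raw p)
    restricts to unambiguous associations before summarising the absolute
    methylation variation explained by genotype and the slope sign skew.
    """
    sub = records[records["simes_snv_raw_p"] < p_threshold]
    if sub.empty:
        return EffectSummary(np.nan, np.nan, np.nan, np.nan, 0)
    return EffectSummary(
        median_delta_x_r2=float(sub["delta_x_r2"].median()),
        sum_delta_x_r2=float(sub["delta_x_r2"].sum()),
        median_r2=float(sub["r2"].median()),
        fraction_b_negative=float((sub["b"] < 0).mean()),
        n_records=len(sub),
    )


def implied_interindividual_range(median_delta_x_r2: float, median_r2: float) -> float:
    """Methylation span implied by a typical association: (delta*R^2) / R^2.

    Dividing the median absolute variation explained by the median R^2
    recovers the implied delta, i.e. the interindividual methylation range
    attributable to genotype for a region of typical effect strength.
    """
    return median_delta_x_r2 / median_r2


def simes_snv_distance_distribution(
    records: pd.DataFrame, breaks_kb: Sequence[float] = (1, 10, 100, 1000)
) -> pd.Series:
    """Cumulative fraction of Simes SNVs within each distance of the region."""
    d = records["snv_distance"].dropna().to_numpy()
    if d.size == 0:
        raise ValueError("no records with a Simes SNV")
    return pd.Series(
        {f"within_{int(kb)}kb": float((d <= kb * 1000).mean()) for kb in breaks_kb}
    )


def cross_tissue_concordance(
    records: pd.DataFrame,
    gset: GenotypeSet,
    blocks: HaplotypeBlockSet,
    require_significant: bool = True,
) -> pd.DataFrame:
    """How often tissues agree on the mQTL signal at each region.

    For regions with records in >= 2 tissues, counts the tissues sharing the
    modal Simes SNV and the modal haplotype block. A SNV outside every block
    counts as its own singleton block (flagged). Block concordance can only
    exceed SNV concordance, since identical SNVs share a block.
    """
    sub = records[records["simes_snv_id"].notna()]
    if require_significant and "significant" in sub.columns:
        sub = sub[sub["significant"]]
    rows = []
    for rid, grp in sub.groupby("region_id"):
        if grp["tissue"].nunique() < 2:
            continue
        snv_counts = grp["simes_snv_id"].value_counts()
        block_ids, unblocked = [], False
        for sid in grp["simes_snv_id"]:
            blk = blocks.block_of_snv(gset.snvs[gset.index_of(sid)])
            if blk is None:
                block_ids.append(f"singleton_{sid}")
                unblocked = True
            else:
                block_ids.append(blk.block_id)
        block_counts = pd.Series(block_ids).value_counts()
        rows.append(
            {
                "region_id": rid,
                "n_tissues": int(grp["tissue"].nunique()),
                "n_tissues_same_snv": int(snv_counts.iloc[0]),
                "n_tissues_same_block": int(block_counts.iloc[0]),
                "snv_outside_block": unblocked,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["region_id", "n_tissues", "n_tissues_same_snv",
                 "n_tissues_same_block", "snv_outside_block"],
    )


def snv_cpg_overlap_robustness(
    records: pd.DataFrame,
    gset: GenotypeSet,
    regions: RegionSet,
    cpg_positions: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Stratify effect sizes by SNV-CpG overlap inside the region.

    A region is "overlapping" when any cohort SNV coincides with either base
    of a CpG dinucleotide inside it (a genotype that physically removes a
    CpG could inflate apparent mQTL). Returns per-stratum slope and R^2
    summaries plus rank-sum p-values for a between-stratum difference; on
    data where effects are not CpG-abrogation artefacts the strata should be
    indistinguishable.
    """
    overlap_status: dict[str, bool] = {}
    for region in regions:
        cpgs = np.asarray(cpg_positions.get(region.region_id, []))
        cpg_bases = set(cpgs.tolist()) | set((cpgs + 1).tolist())
        hit = False
        for snv in gset.snvs:
            if snv.chrom != region.chrom:
                continue
            if region.start <= snv.pos0 < region.end and snv.pos0 in cpg_bases:
                hit = True
                break
        overlap_status[region.region_id] = hit

    sub = records[records["simes_snv_id"].notna()].copy()
    sub["cpg_overlap"] = sub["region_id"].map(overlap_status)
    rows = []
    for label, grp in sub.groupby("cpg_overlap"):
        rows.append(
            {
                "stratum": "overlapping" if label else "no_overlap",
                "n_regions": len(grp),
                "median_b": float(grp["b"].median()),
                "median_abs_b": float(grp["b"].abs().median()),
                "median_r2": float(grp["r2"].median()),
            }
        )
    out = pd.DataFrame(rows)
    a = sub[sub["cpg_overlap"]]
    b = sub[~sub["cpg_overlap"]]
    if len(a) and len(b):
        out.attrs["p_abs_b"] = float(
            stats.mannwhitneyu(a["b"].abs(), b["b"].abs(),
                               alternative="two-sided").pvalue
        )
        out.attrs["p_r2"] = float(
            stats.mannwhitneyu(a["r2"], b["r2"], alternative="two-sided").pvalue
        )
    else:
        out.attrs["p_abs_b"] = np.nan
        out.attrs["p_r2"] = np.nan
    return out
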