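"""Genomic-context statistics around region sets.

Covers: matched-control generation (chromosome / size / CpG-density
matching), sliding-window annotation enrichment out to 50 kb in 1-kb steps,
permutation-based GWAS-SNV overlap enrichment, bootstrap eQTL enrichment,
Tajima's D per region, and rank-sum comparisons of a statistic between
region sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    AnnotationTrack,
    GenotypeSet,
    GwasCatalog,
    Region,
    RegionSet,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# matched controls


def matched_controls(
    query: RegionSet,
    pool: RegionSet,
    seed: int,
    length_tol: float = 0.10,
    density_tol: float = 0.20,
    min_matched_fraction: float = 0.80,
) -> RegionSet:
    """One control per query region, matched on chromosome, length and CpG
    density.

    A pool region is eligible when it shares the chromosome, its length is
    within ``length_tol`` (relative) and its CpG density within
    ``density_tol`` (relative) of the query's. Controls are sampled without
    replacement with a seeded generator; unmatched queries are logged, and
    fewer than ``min_matched_fraction`` matched is an error.
    """
    pool_ids = {r.region_id for r in pool}
    if pool_ids & {r.region_id for r in query}:
        raise ValueError("candidate pool must be disjoint from the query set")
    if len(pool) == 0:
        raise ValueError("candidate pool is empty")
    rng = np.random.default_rng(seed)
    available = list(pool.regions)
    chosen, unmatched = [], []
    for q in query:
        eligible = [
            i for i, c in enumerate(available)
            if c.chrom == q.chrom
            and abs(c.length - q.length) <= length_tol * q.length
            and q.cpg_density > 0
            and abs(c.cpg_density - q.cpg_density) <= density_tol * q.cpg_density
        ]
        if not eligible:
            unmatched.append(q.region_id)
            continue
        pick = eligible[int(rng.integers(len(eligible)))]
        chosen.append(available.pop(pick))
    if unmatched:
        logger.warning("%d query regions unmatched: %s", len(unmatched),
                       unmatched[:10])
    if len(chosen) < min_matched_fraction * len(query):
        raise ValueError(
            f"matched only {len(chosen)}/{len(query)} regions "
            f"(< {min_matched_fraction:.0%})"
        )
    return RegionSet(f"{query.name}_controls", chosen)


# ---------------------------------------------------------------------------
# sliding-window annotation enrichment


def flank_windows(region: Region, d_kb: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """The two 1-kb windows at offset ``d_kb`` from the region boundaries.

    Left: [start - d*1000, start - (d-1)*1000); right:
    [end + (d-1)*1000, end + d*1000). The region body itself is excluded.
    """
    left = (region.start - d_kb * 1000, region.start - (d_kb - 1) * 1000)
    right = (region.end + (d_kb - 1) * 1000, region.end + d_kb * 1000)
    return left, right


def _class_trees(track: AnnotationTrack, by: str) -> dict[str, dict[str, IntervalTree]]:
    trees: dict[str, dict[str, IntervalTree]] = {}
    for row in track.elements.itertuples():
        key = getattr(row, by)
        trees.setdefault(key, {}).setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end
        )
    return trees


def _odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """OR = ad/bc with the Haldane 0.5 correction when any cell is zero."""
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return float(a * d / (b * c)), corrected


def window_enrichment(
    query: RegionSet,
    reference: RegionSet,
    track: AnnotationTrack,
    max_kb: int = 50,
    classes: Optional[Sequence[str]] = None,
    by: str = "cls",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (class, offset) Fisher-exact enrichment of query vs reference.

    At each 1-kb offset d in 1..max_kb, a region is a hit for a class when
    at least one element of the class overlaps either of its two flank
    windows at offset d. The 2x2 table (query vs reference) x (hit vs miss)
    gives a two-sided Fisher exact p and an odds ratio (Haldane-corrected on
    zero cells, flagged); BH adjustment runs across all class x offset cells
    of the profile.
    """
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("query and reference sets must be non-empty")
    if len(track) == 0:
        raise ValueError("annotation track is empty")
    trees = _class_trees(track, by)
    wanted = list(classes) if classes is not None else sorted(trees)
    rows = []
    for cls in wanted:
        if cls not in trees:
            logger.info("class %s absent from track; skipped", cls)
            continue
        ctrees = trees[cls]
        for d in range(1, max_kb + 1):
            counts = {}
            for label, rset in (("query", query), ("reference", reference)):
                hit = 0
                for r in rset:
                    tree = ctrees.get(r.chrom)
                    if tree is None:
                        continue
                    (l0, l1), (r0, r1) = flank_windows(r, d)
                    if tree.overlap(l0, l1) or tree.overlap(r0, r1):
                        hit += 1
                counts[label] = (hit, len(rset) - hit)
            (qh, qm), (rh, rm) = counts["query"], counts["reference"]
            odds, corrected = _odds_ratio(qh, qm, rh, rm)
            p = float(stats.fisher_exact([[qh, qm], [rh, rm]],
                                         alternative="two-sided")[1])
            rows.append(
                {
                    "cls": cls, "offset_kb": d,
                    "query_hit": qh, "query_miss": qm,
                    "reference_hit": rh, "reference_miss": rm,
                    "odds_ratio": odds, "haldane_corrected": corrected, "p": p,
                }
            )
    profile = pd.DataFrame(rows)
    if profile.empty:
        raise ValueError("no testable class in track")
    _, q, _, _ = multipletests(profile["p"], alpha=alpha, method="fdr_bh")
    profile["q"] = q
    profile["significant"] = q < alpha
    return profile


# ---------------------------------------------------------------------------
# GWAS SNV permutation enrichment


@dataclass
class PermutationResult:
    category: str
    observed_overlap: int
    null_overlaps: np.ndarray
    fold: float
    p_perm: float
    p_bonferroni: float


def cis_candidates(
    gset: GenotypeSet, regions: RegionSet, cis_window: int = 1_000_000
) -> dict[str, np.ndarray]:
    """Indices of the cohort SNVs within the cis window of each region."""
    out = {}
    for r in regions:
        idx = [
            i for i, s in enumerate(gset.snvs)
            if s.chrom == r.chrom and r.distance_to(s.pos0) <= cis_window
        ]
        out[r.region_id] = np.array(idx, dtype=int)
    return out


def gwas_permutation(
    mqtl_snvs: dict[str, Sequence[str]],
    catalog: GwasCatalog,
    gset: GenotypeSet,
    regions: RegionSet,
    B: int = 1000,
    seed: int = 0,
    cis_window: int = 1_000_000,
    categories: Optional[Sequence[str]] = None,
    candidates: Optional[dict[str, np.ndarray]] = None,
) -> list[PermutationResult]:
    """Permutation test of mQTL-SNV overlap with GWAS categories.

    ``mqtl_snvs`` maps region_id -> SNV ids attributed to that region.
    Observed = overlap (by chrom+pos) of the pooled mQTL SNVs with the
    category. Each permutation redraws, for every region, the same number of
    SNVs uniformly without replacement from all cohort SNVs within the cis
    window of that region; the per-region overlap count is therefore
    hypergeometric, and the null is the sum of independent per-region draws.
    p_perm = (1 + #{null >= observed}) / (B + 1); Bonferroni across
    categories.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    cands = candidates if candidates is not None else cis_candidates(
        gset, regions, cis_window)
    id_to_idx = {s.snv_id: i for i, s in enumerate(gset.snvs)}
    snv_pos = [(s.chrom, s.pos) for s in gset.snvs]
    cats = list(categories) if categories is not None else list(
        dict.fromkeys(catalog.entries["category"])
    )
    results = []
    for category in cats:
        cat_pos = catalog.positions(category)
        in_cat = np.array([p in cat_pos for p in snv_pos])
        observed = 0
        null = np.zeros(B, dtype=int)
        for rid, snv_ids in mqtl_snvs.items():
            cand = cands.get(rid)
            if cand is None:
                raise ValueError(f"mQTL SNVs attributed to unknown region {rid}")
            k = len(snv_ids)
            if k == 0:
                continue
            for sid in snv_ids:
                observed += int(in_cat[id_to_idx[sid]])
            n_cand = len(cand)
            if k > n_cand:
                logger.warning("region %s: %d mQTL SNVs > %d candidates; sampling all",
                               rid, k, n_cand)
                k = n_cand
            m = int(in_cat[cand].sum())
            if n_cand == 0:
                continue
            null += rng.hypergeometric(m, n_cand - m, k, size=B)
        mean_null = float(null.mean())
        fold = observed / mean_null if mean_null > 0 else math.inf
        p_perm = (1 + int((null >= observed).sum())) / (B + 1)
        results.append(PermutationResult(category, observed, null, fold, p_perm,
                                         min(1.0, p_perm * len(cats))))
    return results


# ---------------------------------------------------------------------------
# eQTL bootstrap enrichment


@dataclass
class BootstrapEnrichment:
    observed_proportion: float
    null_mean: float
    fold: float
    ci_low: float
    ci_high: float


def eqtl_bootstrap(
    simes_snvs: Sequence[str],
    eqtl_lookup: Iterable[str],
    background: Sequence[str],
    B: int = 1000,
    seed: int = 0,
) -> BootstrapEnrichment:
    """Fold enrichment of a SNV set for eQTL membership, by bootstrap.

    Observed: proportion of ``simes_snvs`` in the eQTL lookup. Null: B
    bootstrap samples of the same size from the background; fold = observed
    / mean(null) with a 2.5-97.5 percentile CI of observed / null.
    """
    lookup = set(eqtl_lookup)
    bg = set(background)
    missing = set(simes_snvs) - bg
    if missing:
        raise ValueError(f"background must contain every query SNV; missing "
                         f"{sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    member = np.array([s in lookup for s in background], dtype=float)
    k = len(simes_snvs)
    observed = float(np.mean([s in lookup for s in simes_snvs]))
    null = member[rng.integers(0, len(member), size=(B, k))].mean(axis=1)
    mean_null = float(null.mean())
    if mean_null == 0:
        return BootstrapEnrichment(observed, 0.0, math.nan, math.nan, math.nan)
    with np.errstate(divide="ignore"):
        ratios = np.where(null > 0, observed / null, np.inf)
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return BootstrapEnrichment(observed, mean_null, observed / mean_null,
                               float(lo), float(hi))


# ---------------------------------------------------------------------------
# Tajima's D


@dataclass
class TajimaResult:
    region_id: str
    S: int
    pi: float
    D: float  # NaN when S == 0
    n_chromosomes: int


def tajimas_d(gset: GenotypeSet, region: Region) -> TajimaResult:
    """Tajima's D over the biallelic sites inside one region.

    n = 2 x donors chromosomes. pi is the mean pairwise difference computed
    from allele counts, Sigma_sites 2 k (n - k) / (n (n - 1)); S counts
    sites polymorphic in-sample. D = (pi - S/a1) / sqrt(e1 S + e2 S (S-1))
    with the standard constants as functions of n. D is missing when S = 0.
    """
    n = 2 * len(gset.donors)
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 chromosomes")
    pi = 0.0
    S = 0
    for i, snv in enumerate(gset.snvs):
        if snv.chrom != region.chrom or not (region.start <= snv.pos0 < region.end):
            continue
        g = gset.g[i]
        obs = ~np.isnan(g)
        k = int(g[obs].sum())
        n_site = 2 * int(obs.sum())
        if n_site != n:
            # keep a single n across sites: require complete genotypes
            raise ValueError(
                f"site {snv.snv_id} has missing genotypes; Tajima's D requires "
                "complete data"
            )
        if k == 0 or k == n:
            continue
        S += 1
        pi += 2.0 * k * (n - k) / (n * (n - 1))
    if S == 0:
        return TajimaResult(region.region_id, 0, pi, math.nan, n)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    D = (pi - S / a1) / math.sqrt(var)
    return TajimaResult(region.region_id, S, pi, D, n)


def tajimas_d_scan(gset: GenotypeSet, regions: RegionSet) -> pd.DataFrame:
    rows = [tajimas_d(gset, r).__dict__ for r in regions]
    return pd.DataFrame(rows, columns=["region_id", "S", "pi", "D",
                                       "n_chromosomes"])


# ---------------------------------------------------------------------------
# between-set comparison


def compare_region_sets(
    values: dict[str, Sequence[float]],
    min_values: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney between named value sets.

    Sets with fewer than ``min_values`` finite values are excluded with a
    warning; BH adjustment runs across the pairs.
    """
    clean = {}
    for name, v in values.items():
        arr = np.asarray(list(v), dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr) < min_values:
            logger.warning("set %s has %d values < %d; excluded", name, len(arr),
                           min_values)
            continue
        clean[name] = arr
    if len(clean) < 2:
        raise ValueError("need at least two sets with enough values")
    rows = []
    for a, b in combinations(sorted(clean), 2):
        p = float(stats.mannwhitneyu(clean[a], clean[b],
                                     alternative="two-sided").pvalue)
        rows.append(
            {
                "set_a": a, "set_b": b,
                "median_a": float(np.median(clean[a])),
                "median_b": float(np.median(clean[b])),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["q"] = q
    return out
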