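"""Synthetic cohort generator.

Emulates the statistical structure the downstream analyses assume: donors
genotyped at cis SNVs organised in LD blocks; per-region systemic methylation
driven by a single causal SNV plus a donor random effect shared across
tissues (the systemic component) and independent per-tissue noise; gene
expression linearly coupled to methylation; repeat annotations with
distance-decay enrichment around query regions; and GWAS catalogs with
controlled overlap with causal SNVs.

All functions are deterministic given the config seed; every consumer of
randomness derives its own independent stream from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    GenotypeSet,
    GwasCatalog,
    HaplotypeBlock,
    HaplotypeBlockSet,
    MethylationTensor,
    Region,
    RegionSet,
    Snv,
    AnnotationTrack,
)

DEFAULT_TISSUES = ("blood", "thyroid", "lung", "cerebellum", "skin", "nerve")

DEFAULT_SUBCLASSES = {
    "LINE1": ("L1PA2", "L1PA3"),
    "LTR": ("ERVK", "ERVL"),
    "Alu": ("AluY", "AluSx"),
    "CGI": ("CGI",),
}

GWAS_CATEGORIES = (
    "anthropometric", "cancer", "cardiovascular", "hematological",
    "immune", "metabolic", "neurological", "various",
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a cohort of 500 donors and 100 regions with strong,
    predominantly negative genetic effects on methylation (80% negative
    slopes), a systemic donor effect larger than the per-tissue noise, and
    moderate LD (r = 0.9 between adjacent block SNVs).
    """

    n_donors: int = 500
    n_regions: int = 100
    n_tissues: int = 6
    snvs_per_region_window: int = 40
    snvs_in_region: int = 2
    window_bp: int = 1_000_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    p_negative_beta: float = 0.8
    beta_magnitude_range: tuple[float, float] = (0.05, 0.25)
    sigma_donor: float = 0.04
    sigma_tissue: float = 0.03
    ld_block_size: int = 5
    ld_r: float = 0.9
    expr_coupling: float = 3.0
    expr_noise_sd: float = 0.3
    p_negative_coupling_end: float = 0.8
    region_length: int = 200
    p_within_3kb: float = 0.5
    repeat_lambda0: float = 0.15
    repeat_amplitude: dict[str, float] = field(
        default_factory=lambda: {"LINE1": 6.0, "LTR": 6.0, "Alu": 0.0, "CGI": 0.0}
    )
    repeat_decay_bp: float = 5000.0
    missing_rate: float = 0.0
    n_chromosomes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_negative_beta <= 1:
            raise ValueError("p_negative_beta must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be a subset of (0, 0.5]")
        for name in ("sigma_donor", "sigma_tissue", "expr_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def tissues(self) -> list[str]:
        if self.n_tissues <= len(DEFAULT_TISSUES):
            return list(DEFAULT_TISSUES[: self.n_tissues])
        extra = [f"tissue{i}" for i in range(len(DEFAULT_TISSUES), self.n_tissues)]
        return list(DEFAULT_TISSUES) + extra

    @property
    def donors(self) -> list[str]:
        return [f"donor{i:04d}" for i in range(self.n_donors)]

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named stream of randomness."""
        return np.random.default_rng([int(self.seed), int(stream)])


# stream ids, one per consumer of randomness
_S_REGIONS, _S_GENO, _S_METH, _S_EXPR, _S_ANNOT, _S_GWAS, _S_SITES = range(7)

# spacing between region midpoints; exceeds the cis window plus the
# annotation reach so neighbouring regions do not share SNVs or elements
_SPACING_FACTOR = 1.7


@dataclass
class MethylationSim:
    meth: MethylationTensor
    truth: pd.DataFrame  # region_id, causal_snv_id, b_true, mu, maf, r2_analytic
    clamped_fraction: float


@dataclass
class ExpressionSim:
    expr: pd.DataFrame  # gene_id, donor_id, tissue, value
    truth: pd.DataFrame  # gene_id, region_id, coupling_sign


def simulate_regions(
    cfg: SimulationConfig,
) -> tuple[RegionSet, RegionSet, dict[str, np.ndarray]]:
    """Query regions, a matched-control candidate pool, and CpG positions.

    Regions are spread over ``n_chromosomes`` chromosomes, spaced so cis
    windows never overlap. Each region carries a gene context class
    (``within_3kb_of_end`` with probability ``p_within_3kb``, else
    ``gene_body``). The pool offers three shifted, size/CpG-jittered
    candidates per query region.
    """
    rng = cfg.rng(_S_REGIONS)
    spacing = int(cfg.window_bp * _SPACING_FACTOR)
    per_chrom: dict[str, int] = {}
    queries: list[Region] = []
    pool: list[Region] = []
    cpg_positions: dict[str, np.ndarray] = {}
    for i in range(cfg.n_regions):
        chrom = f"chr{1 + (i % cfg.n_chromosomes)}"
        j = per_chrom.get(chrom, 0)
        per_chrom[chrom] = j + 1
        mid = spacing * (j + 1)
        length = cfg.region_length
        start = mid - length // 2
        end = start + length
        cpg_count = int(rng.integers(5, 16))
        gpc = "within_3kb_of_end" if rng.random() < cfg.p_within_3kb else "gene_body"
        rid = f"region_{i:04d}"
        queries.append(Region(chrom, start, end, rid, cpg_count, f"gene_{i:04d}", gpc))
        cpg_positions[rid] = np.sort(
            rng.choice(np.arange(start, end - 1), size=cpg_count, replace=False)
        )
        for k, offset in enumerate((200_000, 280_000, 360_000)):
            clen = max(50, int(length * rng.uniform(0.92, 1.08)))
            cstart = mid + offset
            density = cpg_count / length
            ccount = max(1, int(round(clen * density * rng.uniform(0.85, 1.15))))
            pool.append(
                Region(chrom, cstart, cstart + clen, f"ctrl_{i:04d}_{k}", ccount)
            )
    return (
        RegionSet("query", queries),
        RegionSet("control_pool", pool),
        cpg_positions,
    )


def simulate_genotypes(
    cfg: SimulationConfig, regions: RegionSet
) -> tuple[GenotypeSet, HaplotypeBlockSet]:
    """Cis SNVs around each region, organised in LD blocks.

    Per region, ``snvs_per_region_window`` SNVs are placed uniformly within
    +/- window_bp/2 of the region midpoint, plus ``snvs_in_region`` SNVs
    inside the region itself. Sorted positions are chunked into blocks of
    ``ld_block_size``; within a block, each haplotype is a copy chain: allele
    j+1 copies allele j with probability ``ld_r``, else is redrawn at the
    block allele frequency, giving adjacent-SNV allele correlation ld_r.
    """
    rng = cfg.rng(_S_GENO)
    snvs: list[Snv] = []
    hap_rows: list[np.ndarray] = []
    blocks: list[HaplotypeBlock] = []
    half = cfg.window_bp // 2
    for r in regions:
        n_window = cfg.snvs_per_region_window
        pos_window = rng.choice(
            np.arange(r.midpoint - half, r.midpoint + half),
            size=n_window, replace=False,
        )
        pos_inside = (
            rng.choice(np.arange(r.start, r.end), size=cfg.snvs_in_region,
                       replace=False)
            if cfg.snvs_in_region > 0
            else np.array([], dtype=int)
        )
        pos0 = np.sort(np.concatenate([pos_window, pos_inside]).astype(int))
        # block boundaries never straddle the region: SNVs inside the region
        # share one block, so the block overlapping the region carries the
        # causal SNV (identifiable truth for the haplotype analysis)
        groups = [
            pos0[pos0 < r.start],
            pos0[(pos0 >= r.start) & (pos0 < r.end)],
            pos0[pos0 >= r.end],
        ]
        chunks: list[np.ndarray] = []
        for grp in groups:
            for b0 in range(0, len(grp), cfg.ld_block_size):
                chunks.append(grp[b0 : b0 + cfg.ld_block_size])
        for chunk_no, chunk in enumerate(chunks):
            if len(chunk) == 0:
                continue
            p = rng.uniform(*cfg.maf_range)
            m = len(chunk)
            # two haplotypes per donor, chained within the block
            hap = np.zeros((m, cfg.n_donors, 2), dtype=int)
            hap[0] = rng.random((cfg.n_donors, 2)) < p
            for j in range(1, m):
                copy = rng.random((cfg.n_donors, 2)) < cfg.ld_r
                fresh = rng.random((cfg.n_donors, 2)) < p
                hap[j] = np.where(copy, hap[j - 1], fresh)
            ids = []
            for j, pz in enumerate(chunk):
                sid = f"snv_{r.region_id}_{len(snvs):05d}"
                snvs.append(Snv(sid, r.chrom, int(pz) + 1, "A", "G", float(p)))
                hap_rows.append(hap[j])
                ids.append(sid)
            blocks.append(
                HaplotypeBlock(
                    r.chrom, int(chunk[0]), int(chunk[-1]) + 1,
                    f"block_{r.region_id}_{chunk_no:03d}",
                    tuple(ids),
                )
            )
    haps = np.stack(hap_rows)
    g = haps.sum(axis=2).astype(float)
    return GenotypeSet(snvs, cfg.donors, g, haps), HaplotypeBlockSet(blocks)


def _causal_index(gset: GenotypeSet, region: Region) -> int:
    """Index of the SNV nearest to the region (ties to the lowest position)."""
    best, best_d = -1, None
    for i, s in enumerate(gset.snvs):
        if s.chrom != region.chrom:
            continue
        d = region.distance_to(s.pos0)
        if best_d is None or d < best_d or (d == best_d and s.pos < gset.snvs[best].pos):
            best, best_d = i, d
    return best


def simulate_methylation(
    cfg: SimulationConfig, gset: GenotypeSet, regions: RegionSet
) -> MethylationSim:
    """Systemic methylation: one causal SNV per region.

    beta(r, d, t) = clamp01(mu_r + b_r * g + u_{d,r} + eps_{d,r,t}) with u
    the donor effect shared across tissues and eps the tissue noise. Slope
    signs are negative for an exact ``p_negative_beta`` share of regions
    (seeded random assignment), making the generative sign skew a fixed
    condition rather than a binomial draw; magnitudes are uniform in
    ``beta_magnitude_range``. mu_r centres the expected methylation at 0.5
    so the [0, 1] clamp is rarely hit (the clamped fraction is reported).
    """
    rng = cfg.rng(_S_METH)
    n_r, n_d, n_t = len(regions), cfg.n_donors, cfg.n_tissues
    n_neg = int(round(cfg.p_negative_beta * n_r))
    signs = np.concatenate([-np.ones(n_neg), np.ones(n_r - n_neg)])
    rng.shuffle(signs)
    magnitudes = rng.uniform(*cfg.beta_magnitude_range, size=n_r)
    b = signs * magnitudes

    values = np.zeros((n_r, n_d, n_t))
    truth_rows = []
    for i, r in enumerate(regions):
        ci = _causal_index(gset, r)
        snv = gset.snvs[ci]
        g = np.nan_to_num(gset.g[ci], nan=0.0)
        mu = 0.5 - b[i] * 2 * snv.maf
        u = rng.normal(0.0, cfg.sigma_donor, size=n_d)
        eps = rng.normal(0.0, cfg.sigma_tissue, size=(n_d, n_t))
        values[i] = (mu + b[i] * g + u)[:, None] + eps
        var_g = 2 * snv.maf * (1 - snv.maf)
        denom = b[i] ** 2 * var_g + cfg.sigma_donor**2 + cfg.sigma_tissue**2
        truth_rows.append(
            {
                "region_id": r.region_id,
                "causal_snv_id": snv.snv_id,
                "b_true": b[i],
                "mu": mu,
                "maf": snv.maf,
                "r2_analytic": (b[i] ** 2 * var_g) / denom if denom > 0 else 0.0,
            }
        )
    clamped = float(np.mean((values < 0) | (values > 1)))
    values = np.clip(values, 0.0, 1.0)
    mask = np.ones_like(values, dtype=bool)
    if cfg.missing_rate > 0:
        mask &= rng.random(values.shape) >= cfg.missing_rate
    meth = MethylationTensor(
        [r.region_id for r in regions], cfg.donors, cfg.tissues, values, mask
    )
    return MethylationSim(meth, pd.DataFrame(truth_rows), clamped)


def simulate_expression(
    cfg: SimulationConfig, meth: MethylationTensor, regions: RegionSet
) -> ExpressionSim:
    """One gene per region, linearly coupled to that region's methylation.

    expression = a_r + expr_coupling * c_r * beta + noise. The coupling sign
    c_r is -1 with probability ``p_negative_coupling_end`` for regions near a
    gene end, else a fair +/-1 draw, planting the positional sign bias that
    the odds-ratio analysis recovers.
    """
    rng = cfg.rng(_S_EXPR)
    rows, truth = [], []
    for r in regions:
        gene = r.gene_id or f"gene_{r.region_id}"
        a = rng.uniform(2.0, 8.0)
        if r.gene_position_class == "within_3kb_of_end":
            c = -1 if rng.random() < cfg.p_negative_coupling_end else 1
        else:
            c = -1 if rng.random() < 0.5 else 1
        i = meth.region_index(r.region_id)
        for k, tissue in enumerate(meth.tissues):
            noise = rng.normal(0.0, cfg.expr_noise_sd, size=len(meth.donors))
            vals = a + cfg.expr_coupling * c * meth.values[i, :, k] + noise
            for j, donor in enumerate(meth.donors):
                if meth.mask[i, j, k]:
                    rows.append((gene, donor, tissue, float(vals[j])))
        truth.append({"gene_id": gene, "region_id": r.region_id, "coupling_sign": c})
    expr = pd.DataFrame(rows, columns=["gene_id", "donor_id", "tissue", "value"])
    return ExpressionSim(expr, pd.DataFrame(truth))


def simulate_annotations(
    cfg: SimulationConfig, query: RegionSet, controls: RegionSet
) -> AnnotationTrack:
    """Repeat/CGI elements with distance-decay intensity around queries.

    In each 1-kb flank bin at offset d (bin centre distance d_c bp) around a
    query region, per-class element counts are Poisson with mean
    lambda0 * (1 + A_class * exp(-d_c / repeat_decay_bp)); around control
    regions the intensity is the flat lambda0.
    """
    rng = cfg.rng(_S_ANNOT)
    rows = []
    max_kb = 50

    def emit(region: Region, enriched: bool) -> None:
        for cls, amp in cfg.repeat_amplitude.items():
            subclasses = DEFAULT_SUBCLASSES.get(cls, (cls,))
            for d in range(1, max_kb + 1):
                centre = (d - 0.5) * 1000.0
                lam = cfg.repeat_lambda0
                if enriched:
                    lam *= 1.0 + amp * np.exp(-centre / cfg.repeat_decay_bp)
                for side in (-1, 1):
                    n = rng.poisson(lam)
                    for _ in range(n):
                        if side < 0:
                            lo = region.start - d * 1000
                        else:
                            lo = region.end + (d - 1) * 1000
                        start = int(rng.integers(lo, lo + 1000))
                        length = int(rng.integers(100, 400))
                        rows.append(
                            (
                                region.chrom, start, start + length, cls,
                                subclasses[int(rng.integers(len(subclasses)))],
                            )
                        )

    for r in query:
        emit(r, enriched=True)
    for r in controls:
        emit(r, enriched=False)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cls", "subclass"])
    return AnnotationTrack(df)


def simulate_gwas_catalog(
    cfg: SimulationConfig,
    gset: GenotypeSet,
    mqtl_snv_ids: Sequence[str],
    enrichment_fold: dict[str, float],
    category_size: int = 300,
    rng: Optional[np.random.Generator] = None,
) -> GwasCatalog:
    """Category SNV sets sampled from the cohort SNVs.

    SNVs in ``mqtl_snv_ids`` receive sampling weight ``enrichment_fold``
    for their category (fold 1 = uniform null). Categories are sampled
    independently, without replacement within a category.
    """
    if rng is None:
        rng = cfg.rng(_S_GWAS)
    ids = np.array(gset.snv_ids)
    is_mqtl = np.isin(ids, list(mqtl_snv_ids))
    rows = []
    for category in sorted(enrichment_fold):
        fold = enrichment_fold[category]
        if fold < 0:
            raise ValueError("enrichment_fold must be >= 0")
        w = np.where(is_mqtl, float(fold), 1.0)
        w = w / w.sum()
        take = rng.choice(len(ids), size=min(category_size, len(ids)),
                          replace=False, p=w)
        for i in take:
            s = gset.snvs[i]
            rows.append((s.chrom, s.pos, s.snv_id, category))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "snv_id", "category"])
    cats = tuple(sorted(set(enrichment_fold) | set(GWAS_CATEGORIES)))
    return GwasCatalog(df, cats)


def simulate_region_sites(
    regions: RegionSet,
    sites_per_region: int,
    maf_range: tuple[float, float],
    n_donors: int,
    seed: int,
) -> GenotypeSet:
    """Independent biallelic sites inside each region (for diversity stats).

    Site frequencies are uniform in ``maf_range``; haplotypes are drawn
    independently per site (no LD), 2 per donor.
    """
    rng = np.random.default_rng([int(seed), _S_SITES])
    snvs, hap_rows = [], []
    donors = [f"donor{i:04d}" for i in range(n_donors)]
    for r in regions:
        k = min(sites_per_region, r.length)
        pos0 = np.sort(rng.choice(np.arange(r.start, r.end), size=k, replace=False))
        for j, pz in enumerate(pos0):
            p = rng.uniform(*maf_range)
            hap = (rng.random((n_donors, 2)) < p).astype(int)
            snvs.append(
                Snv(f"site_{r.region_id}_{j:03d}", r.chrom, int(pz) + 1, "A", "G",
                    float(p))
            )
            hap_rows.append(hap)
    haps = np.stack(hap_rows) if hap_rows else np.full((0, n_donors, 2), -1)
    g = haps.sum(axis=2).astype(float) if hap_rows else np.zeros((0, n_donors))
    return GenotypeSet(snvs, donors, g, haps if hap_rows else None)
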