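"""Readers and writers for the on-disk formats shared by all stages.

Formats: BED (3+ columns) for regions, annotation tracks and haplotype
blocks; VCF for genotypes; headered TSV for methylation, expression and GWAS
catalogs. BED intervals are 0-based half-open; VCF positions 1-based. All
writers emit a deterministic column and line order so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    GENE_END_PROXIMITY_BP,
    AnnotationTrack,
    GenotypeSet,
    GwasCatalog,
    HaplotypeBlock,
    HaplotypeBlockSet,
    MethylationTensor,
    Region,
    RegionSet,
    Snv,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised for malformed input lines; message names the offending line."""


# ---------------------------------------------------------------------------
# regions


def classify_gene_position(
    chrom: str, start: int, end: int, gene_table: pd.DataFrame
) -> tuple[str, Optional[str]]:
    """Gene-context class of an interval against a gene table.

    ``within_3kb_of_end`` if the region start or end lies within 3 kb of a
    gene's 5' or 3' terminus; otherwise ``gene_body`` if the region overlaps
    a gene; otherwise ``none``.
    """
    genes = gene_table[gene_table["chrom"] == chrom]
    body_gene = None
    for g in genes.itertuples():
        near_end = min(
            abs(start - g.start), abs(start - g.end),
            abs(end - g.start), abs(end - g.end),
        ) <= GENE_END_PROXIMITY_BP
        if near_end:
            return "within_3kb_of_end", str(g.gene_id)
        if body_gene is None and start < g.end and end > g.start:
            body_gene = str(g.gene_id)
    if body_gene is not None:
        return "gene_body", body_gene
    return "none", None


def read_regions(
    path: PathLike,
    name: Optional[str] = None,
    gene_table: Optional[pd.DataFrame] = None,
) -> RegionSet:
    """Read a BED-like file into a :class:`RegionSet`.

    Columns: chrom, start, end[, region_id[, cpg_count[, gene_position_class
    [, gene_id]]]]. When ``gene_table`` (columns chrom, start, end, gene_id)
    is given, the gene-context class is (re)computed from it.
    """
    path = Path(path)
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start ({start}) >= end ({end})")
            region_id = parts[3] if len(parts) > 3 else f"region_{lineno}"
            cpg_count = int(parts[4]) if len(parts) > 4 and parts[4] != "." else 0
            gpc = parts[5] if len(parts) > 5 and parts[5] != "." else "none"
            gene_id = parts[6] if len(parts) > 6 and parts[6] != "." else None
            if gene_table is not None:
                gpc, gene_id = classify_gene_position(chrom, start, end, gene_table)
            regions.append(
                Region(chrom, start, end, region_id, cpg_count, gene_id, gpc)
            )
    return RegionSet(name or path.stem, regions)


def write_regions(region_set: RegionSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in region_set:
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.start),
                        str(r.end),
                        r.region_id,
                        str(r.cpg_count),
                        r.gene_position_class,
                        r.gene_id if r.gene_id is not None else ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# annotation tracks and haplotype blocks


def read_annotations(path: PathLike) -> AnnotationTrack:
    """BED with class (4th) and subclass (5th) columns."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "cls", "subclass"],
        dtype={"chrom": str, "start": int, "end": int, "cls": str, "subclass": str},
    )
    return AnnotationTrack(df)


def write_annotations(track: AnnotationTrack, path: PathLike) -> None:
    df = track.elements.sort_values(
        ["chrom", "start", "end", "cls", "subclass"], kind="mergesort"
    )
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "cls", "subclass"])


def read_haplotype_blocks(path: PathLike) -> HaplotypeBlockSet:
    """BED: chrom, start, end, block_id, comma-separated snv_ids."""
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            blocks.append(
                HaplotypeBlock(
                    parts[0], int(parts[1]), int(parts[2]), parts[3],
                    tuple(parts[4].split(",")) if parts[4] else (),
                )
            )
    return HaplotypeBlockSet(blocks)


def write_haplotype_blocks(blocks: HaplotypeBlockSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t{b.block_id}\t{','.join(b.snv_ids)}\n"
            )


# ---------------------------------------------------------------------------
# GWAS catalog


def read_gwas_catalog(path: PathLike, categories: Sequence[str]) -> GwasCatalog:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int,
                                            "snv_id": str, "category": str})
    return GwasCatalog(df, tuple(categories))


def write_gwas_catalog(catalog: GwasCatalog, path: PathLike) -> None:
    df = catalog.entries.sort_values(
        ["category", "chrom", "pos", "snv_id"], kind="mergesort"
    )
    df.to_csv(path, sep="\t", index=False,
              columns=["chrom", "pos", "snv_id", "category"])


# ---------------------------------------------------------------------------
# methylation / expression tables


def read_methylation(path: PathLike) -> MethylationTensor:
    """Long TSV (region_id, donor_id, tissue, beta) -> tensor with mask."""
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str, "donor_id": str,
                                            "tissue": str})
    return methylation_from_long(df)


def methylation_from_long(df: pd.DataFrame) -> MethylationTensor:
    regions = sorted(df["region_id"].unique())
    donors = sorted(df["donor_id"].unique())
    tissues = sorted(df["tissue"].unique())
    ridx = {r: i for i, r in enumerate(regions)}
    didx = {d: i for i, d in enumerate(donors)}
    tidx = {t: i for i, t in enumerate(tissues)}
    values = np.zeros((len(regions), len(donors), len(tissues)))
    mask = np.zeros_like(values, dtype=bool)
    for row in df.itertuples():
        i, j, k = ridx[row.region_id], didx[row.donor_id], tidx[row.tissue]
        values[i, j, k] = row.beta
        mask[i, j, k] = True
    return MethylationTensor(regions, donors, tissues, values, mask)


def write_methylation(meth: MethylationTensor, path: PathLike) -> None:
    meth.to_long().to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_expression(path: PathLike) -> pd.DataFrame:
    """Long TSV (gene_id, donor_id, tissue, value)."""
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "donor_id": str,
                                              "tissue": str})


def write_expression(expr: pd.DataFrame, path: PathLike) -> None:
    expr.sort_values(["gene_id", "donor_id", "tissue"], kind="mergesort").to_csv(
        path, sep="\t", index=False, float_format="%.6f",
        columns=["gene_id", "donor_id", "tissue", "value"],
    )


# ---------------------------------------------------------------------------
# genotypes (VCF)


def read_genotypes(
    path: PathLike, donor_subset: Optional[Sequence[str]] = None
) -> GenotypeSet:
    """Read a VCF into a :class:`GenotypeSet` with MINOR-allele coding.

    The minor allele is the allele with sample frequency <= 0.5 among the
    loaded donors (ties broken toward alt). Multi-allelic records are skipped
    with a warning; missing GT fields become NaN cells. Phase is retained
    when the GT separator is ``|``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if donor_subset is not None:
        missing = [d for d in donor_subset if d not in samples]
        if missing:
            raise ValueError(f"donors absent from VCF header: {missing}")
        keep = [samples.index(d) for d in donor_subset]
        donors = list(donor_subset)
    else:
        keep = list(range(len(samples)))
        donors = samples

    snvs: list[Snv] = []
    alt_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic record at %s:%d", var.CHROM, var.POS)
            continue
        gts = var.genotypes  # list of [a0, a1, phased]
        alt_count = np.full(len(keep), np.nan)
        haps = np.full((len(keep), 2), -1, dtype=int)
        for out_i, samp_i in enumerate(keep):
            a0, a1, phased = gts[samp_i][0], gts[samp_i][1], gts[samp_i][2]
            if a0 < 0 or a1 < 0:
                continue
            alt_count[out_i] = a0 + a1
            if phased:
                haps[out_i] = (a0, a1)
        obs = ~np.isnan(alt_count)
        if obs.sum() == 0:
            alt_freq = 0.0
        else:
            alt_freq = float(alt_count[obs].sum()) / (2 * int(obs.sum()))
        if alt_freq <= 0.5:
            minor_is_alt, maf = True, alt_freq
        else:
            minor_is_alt, maf = False, 1.0 - alt_freq
        g = alt_count if minor_is_alt else 2.0 - alt_count
        if not minor_is_alt:
            flip = haps >= 0
            haps = np.where(flip, 1 - haps, haps)
        snv_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snvs.append(Snv(snv_id, var.CHROM, var.POS, var.REF, var.ALT[0], maf))
        alt_rows.append(g)
        hap_rows.append(haps)

    g = np.array(alt_rows) if alt_rows else np.zeros((0, len(donors)))
    haps = np.array(hap_rows) if hap_rows else np.full((0, len(donors), 2), -1)
    return GenotypeSet(snvs, donors, g, haps)


def write_genotypes(gset: GenotypeSet, path: PathLike) -> None:
    """Write a minimal VCF with GT fields, the cohort minor allele as ALT.

    Records whose in-memory "minor" coding has an empirical frequency above
    0.5 in this cohort are flipped on output (ref/alt swapped), so the file
    is in canonical cohort-relative coding and a round trip through
    :func:`read_genotypes` reproduces the written matrix exactly.
    """
    order = sorted(range(len(gset.snvs)),
                   key=lambda i: (gset.snvs[i].chrom, gset.snvs[i].pos))
    chroms = sorted({s.chrom for s in gset.snvs})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gset.donors) + "\n")
        for i in order:
            snv = gset.snvs[i]
            g = gset.g[i]
            obs = ~np.isnan(g)
            freq = float(g[obs].sum()) / (2 * int(obs.sum())) if obs.any() else 0.0
            flip = freq > 0.5
            ref, alt = (snv.alt, snv.ref) if flip else (snv.ref, snv.alt)
            fields = [snv.chrom, str(snv.pos), snv.snv_id, ref, alt,
                      ".", "PASS", ".", "GT"]
            for j in range(len(gset.donors)):
                gij = g[j]
                if np.isnan(gij):
                    fields.append("./.")
                    continue
                if gset.haplotypes is not None and np.all(gset.haplotypes[i, j] >= 0):
                    a, b = gset.haplotypes[i, j]
                    if flip:
                        a, b = 1 - a, 1 - b
                    fields.append(f"{a}|{b}")
                else:
                    gij = int(2 - gij) if flip else int(gij)
                    fields.append({0: "0/0", 1: "0/1", 2: "1/1"}[gij])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# per-sample methylation aggregation and the M-value transform


def region_methylation(
    cpg_table: pd.DataFrame, regions: RegionSet, min_depth: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Coverage-weighted region methylation for one donor/tissue sample.

    ``cpg_table`` columns: chrom, pos (0-based C position), n_meth, n_unmeth.
    Returns (values, mask) aligned with ``regions``; a region is masked
    missing when its summed depth is below ``min_depth`` (or it has no CpGs).
    """
    if (cpg_table[["n_meth", "n_unmeth"]] < 0).any().any():
        raise ValueError("CpG counts must be non-negative")
    values = np.zeros(len(regions))
    mask = np.zeros(len(regions), dtype=bool)
    for i, r in enumerate(regions):
        sub = cpg_table[
            (cpg_table["chrom"] == r.chrom)
            & (cpg_table["pos"] >= r.start)
            & (cpg_table["pos"] < r.end)
        ]
        if sub.empty:
            logger.info("region %s has no covered CpGs; masked", r.region_id)
            continue
        depth = int(sub["n_meth"].sum() + sub["n_unmeth"].sum())
        if depth < min_depth:
            logger.info("region %s depth %d < %d; masked", r.region_id, depth, min_depth)
            continue
        values[i] = float(sub["n_meth"].sum()) / depth
        mask[i] = True
    return values, mask


def m_transform(beta, epsilon: float = 0.001):
    """M value: log2(b/(1-b)) with b clamped to [epsilon, 1-epsilon].

    Variance-stabilising logit transform of the beta value; the clamp keeps
    fully (un)methylated regions finite.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1 - epsilon)
    out = np.log2(b / (1 - b))
    if np.isscalar(beta) or np.asarray(beta).ndim == 0:
        return float(out)
    return out
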