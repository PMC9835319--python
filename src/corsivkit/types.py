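"""Domain containers shared by every analysis stage.

Coordinate conventions: BED-style 0-based half-open intervals everywhere in
memory; VCF positions are converted from 1-based at the read boundary.
Methylation is stored as a fraction (beta value) in [0, 1]; percent appears
only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

GENE_POSITION_CLASSES = ("gene_body", "within_3kb_of_end", "none")

#: distance (bp) from a gene terminus within which a region is classed as
#: ``within_3kb_of_end``
GENE_END_PROXIMITY_BP = 3000


@dataclass(frozen=True)
class Region:
    """A named genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    region_id: str
    cpg_count: int = 0
    gene_id: Optional[str] = None
    gene_position_class: str = "none"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"region {self.region_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.cpg_count < 0:
            raise ValueError(f"region {self.region_id}: cpg_count must be >= 0")
        if self.gene_position_class not in GENE_POSITION_CLASSES:
            raise ValueError(
                f"region {self.region_id}: unknown gene_position_class "
                f"{self.gene_position_class!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def cpg_density(self) -> float:
        return self.cpg_count / self.length

    def distance_to(self, pos0: int) -> int:
        """Distance (bp) from a 0-based position to the nearest base of the
        region; 0 if the position lies inside the interval."""
        if pos0 < self.start:
            return self.start - pos0
        if pos0 >= self.end:
            return pos0 - (self.end - 1)
        return 0


@dataclass
class RegionSet:
    """An ordered collection of uniquely named regions."""

    name: str
    regions: list[Region]

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            dup = dup[dup > 1].index.tolist()
            raise ValueError(f"duplicate region_id(s) in set {self.name!r}: {dup}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def get(self, region_id: str) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "region_id": [r.region_id for r in self.regions],
                "cpg_count": [r.cpg_count for r in self.regions],
                "gene_id": [r.gene_id for r in self.regions],
                "gene_position_class": [r.gene_position_class for r in self.regions],
            }
        )


@dataclass
class MethylationTensor:
    """region x donor x tissue average methylation fractions with a mask.

    ``values[i, j, k]`` is the beta value of region ``regions[i]`` in donor
    ``donors[j]``, tissue ``tissues[k]``; ``mask`` is True where observed.
    """

    regions: list[str]
    donors: list[str]
    tissues: list[str]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        expected = (len(self.regions), len(self.donors), len(self.tissues))
        if self.values.shape != expected or self.mask.shape != expected:
            raise ValueError(
                f"methylation tensor shape {self.values.shape} does not match "
                f"index lists {expected}"
            )
        observed = self.values[self.mask]
        if observed.size and (observed.min() < 0 or observed.max() > 1):
            raise ValueError("observed methylation values must lie in [0, 1]")

    def region_index(self, region_id: str) -> int:
        return self.regions.index(region_id)

    def tissue_index(self, tissue: str) -> int:
        return self.tissues.index(tissue)

    def slice(self, region_id: str, tissue: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-donor values and observation mask for one region/tissue."""
        i = self.region_index(region_id)
        k = self.tissue_index(tissue)
        return self.values[i, :, k], self.mask[i, :, k]

    def to_long(self) -> pd.DataFrame:
        recs = []
        for i, rid in enumerate(self.regions):
            for j, did in enumerate(self.donors):
                for k, tis in enumerate(self.tissues):
                    if self.mask[i, j, k]:
                        recs.append((rid, did, tis, float(self.values[i, j, k])))
        return pd.DataFrame(recs, columns=["region_id", "donor_id", "tissue", "beta"])


@dataclass(frozen=True)
class Snv:
    snv_id: str
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    maf: float

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass
class GenotypeSet:
    """SNV metadata plus a donor genotype matrix of minor-allele counts.

    ``g[s, d]`` in {0, 1, 2} or NaN for missing. ``haplotypes[s, d, :]`` holds
    the two phased minor-allele indicators (-1 where unphased/missing).
    """

    snvs: list[Snv]
    donors: list[str]
    g: np.ndarray
    haplotypes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.g.shape != (len(self.snvs), len(self.donors)):
            raise ValueError("genotype matrix shape does not match snv/donor lists")
        if self.haplotypes is not None:
            if self.haplotypes.shape != (len(self.snvs), len(self.donors), 2):
                raise ValueError("haplotype array shape must be (n_snvs, n_donors, 2)")
            both = np.all(self.haplotypes >= 0, axis=2)
            hsum = self.haplotypes.sum(axis=2)
            ok = ~both | np.isnan(self.g) | (hsum == self.g)
            if not ok.all():
                raise ValueError("phased haplotypes inconsistent with genotype counts")

    def __len__(self) -> int:
        return len(self.snvs)

    @property
    def snv_ids(self) -> list[str]:
        return [s.snv_id for s in self.snvs]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.snvs], dtype=int)

    def index_of(self, snv_id: str) -> int:
        return self.snv_ids.index(snv_id)

    def subset_donors(self, donors: Sequence[str]) -> "GenotypeSet":
        idx = [self.donors.index(d) for d in donors]
        hap = self.haplotypes[:, idx, :] if self.haplotypes is not None else None
        return GenotypeSet(self.snvs, list(donors), self.g[:, idx], hap)


@dataclass
class AnnotationTrack:
    """Repeat / CpG-island elements: chrom, start, end, class, subclass."""

    elements: pd.DataFrame  # columns chrom, start, end, cls, subclass

    REQUIRED = ("chrom", "start", "end", "cls", "subclass")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.elements.columns]
        if missing:
            raise ValueError(f"annotation track missing columns {missing}")
        if len(self.elements):
            if (self.elements["start"] >= self.elements["end"]).any():
                raise ValueError("annotation intervals must satisfy start < end")
            if (self.elements["cls"].astype(str).str.len() == 0).any():
                raise ValueError("annotation class labels must be non-empty")

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def classes(self) -> list[str]:
        return sorted(self.elements["cls"].unique())


@dataclass(frozen=True)
class HaplotypeBlock:
    chrom: str
    start: int
    end: int
    block_id: str
    snv_ids: tuple[str, ...]

    def overlap_bp(self, region: Region) -> int:
        if region.chrom != self.chrom:
            return 0
        return max(0, min(self.end, region.end) - max(self.start, region.start))


@dataclass
class HaplotypeBlockSet:
    blocks: list[HaplotypeBlock]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[HaplotypeBlock]] = {}
        for b in self.blocks:
            by_chrom.setdefault(b.chrom, []).append(b)
        for chrom, bs in by_chrom.items():
            bs = sorted(bs, key=lambda b: b.start)
            for a, b in zip(bs, bs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"haplotype blocks {a.block_id} and {b.block_id} overlap on {chrom}"
                    )

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def block_of_snv(self, snv: Snv) -> Optional[HaplotypeBlock]:
        """Block containing the SNV position (by coordinate lookup)."""
        for b in self.blocks:
            if b.chrom == snv.chrom and b.start <= snv.pos0 < b.end:
                return b
        return None


@dataclass
class GwasCatalog:
    """GWAS SNVs with a disease/phenotype category label."""

    entries: pd.DataFrame  # columns chrom, pos, snv_id, category
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        for col in ("chrom", "pos", "snv_id", "category"):
            if col not in self.entries.columns:
                raise ValueError(f"GWAS catalog missing column {col!r}")
        bad = set(self.entries["category"]) - set(self.categories)
        if bad:
            raise ValueError(f"GWAS catalog categories outside vocabulary: {sorted(bad)}")

    def positions(self, category: str) -> set[tuple[str, int]]:
        sub = self.entries[self.entries["category"] == category]
        if sub.empty:
            raise ValueError(f"GWAS category {category!r} is empty")
        return set(zip(sub["chrom"], sub["pos"].astype(int)))
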