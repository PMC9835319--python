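"""End-to-end orchestration: one config, seeded stages, TSV + JSON reports.

The pipeline runs (as toggled): simulate -> siv -> mqtl -> haplo -> methexpr
-> enrich -> gwasperm -> tajima. Each stage writes its tables under the
output directory and appends a JSON-lines entry (stage, parameters, seed,
row counts, wall time) to ``run_log.jsonl``; a final ``summary.json``
collates the headline statistics.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import enrichment, haplotype, io, methexpr, mqtl, siv
from .simulate import (
    GWAS_CATEGORIES,
    SimulationConfig,
    simulate_annotations,
    simulate_expression,
    simulate_genotypes,
    simulate_gwas_catalog,
    simulate_methylation,
    simulate_region_sites,
    simulate_regions,
)

ALL_STAGES = ("simulate", "siv", "mqtl", "haplo", "methexpr", "enrich",
              "gwasperm", "tajima")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


_SECTION_KEYS = {
    "seed": None,
    "stages": None,
    "inputs": {"regions", "control_pool", "vcf", "methylation", "expression",
               "annotations", "blocks", "gwas_catalog"},
    "simulate": {f.name for f in dataclasses.fields(SimulationConfig)},
    "siv": {"min_pair_donors", "siv_r_threshold"},
    "mqtl": {"cis_window", "min_donors", "scale", "alpha", "p_threshold",
             "tissues"},
    "haplo": {"min_donors", "tissue"},
    "methexpr": {"target_tissue", "surrogate_tissue", "alpha", "min_level",
                 "min_tissues", "min_donors"},
    "enrich": {"max_kb", "alpha"},
    "gwasperm": {"B", "category_size", "enrichment_fold"},
    "tajima": {"sites_per_region", "maf_range_query", "maf_range_control"},
}


@dataclass
class PipelineConfig:
    seed: int
    stages: list[str]
    inputs: dict[str, str] = field(default_factory=dict)
    simulate: dict[str, Any] = field(default_factory=dict)
    siv: dict[str, Any] = field(default_factory=dict)
    mqtl: dict[str, Any] = field(default_factory=dict)
    haplo: dict[str, Any] = field(default_factory=dict)
    methexpr: dict[str, Any] = field(default_factory=dict)
    enrich: dict[str, Any] = field(default_factory=dict)
    gwasperm: dict[str, Any] = field(default_factory=dict)
    tajima: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - set(_SECTION_KEYS)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigError("config must set an explicit seed")
        for section, allowed in _SECTION_KEYS.items():
            if allowed is None or section not in raw:
                continue
            bad = set(raw[section]) - allowed
            if bad:
                raise ConfigError(f"unknown key(s) in [{section}]: {sorted(bad)}")
        stages = raw.get("stages", [])
        bad = set(stages) - set(ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stage(s): {sorted(bad)}")
        return cls(
            seed=int(raw["seed"]),
            stages=list(stages),
            **{k: raw.get(k, {}) for k in _SECTION_KEYS
               if k not in ("seed", "stages")},
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, outdir) -> dict[str, Any]:
    """Run the toggled stages; return (and write) the summary report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.jsonl"
    summary: dict[str, Any] = {"seed": config.seed, "stages": config.stages}
    state: dict[str, Any] = {}

    def log(stage: str, params: dict, t0: float, **counts) -> None:
        entry = {"stage": stage, "parameters": params, "seed": config.seed,
                 "wall_time_s": round(time.perf_counter() - t0, 3), **counts}
        with open(log_path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")

    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                _stage_simulate(config, outdir, state)
                log(stage, config.simulate, t0,
                    n_regions=len(state["regions"]),
                    n_snvs=len(state["genotypes"]),
                    clamped_fraction=state["clamped_fraction"])
            elif stage == "siv":
                _load_inputs(config, state)
                params = {"min_pair_donors": config.siv.get("min_pair_donors", 10),
                          "siv_r_threshold": config.siv.get("siv_r_threshold", 0.6)}
                report = siv.intertissue_correlations(state["meth"], **params)
                report.summary.to_csv(outdir / "siv_summary.tsv", sep="\t",
                                      index=False)
                report.pair_correlations.to_csv(outdir / "siv_pairs.tsv", sep="\t",
                                                index=False)
                siv_regions = [r for r in state["regions"]
                               if report.summary.set_index("region_id")
                               .loc[r.region_id, "is_siv"]]
                if siv_regions:
                    io.write_regions(
                        type(state["regions"])("siv", siv_regions),
                        outdir / "siv_regions.bed",
                    )
                clust = siv.donor_clustering(state["meth"])
                (outdir / "donor_clustering.nwk").write_text(
                    siv.linkage_to_newick(
                        clust.linkage,
                        [f"{d}|{t}" for d, t in clust.sample_labels],
                    )
                )
                summary["siv_fraction"] = float(report.summary["is_siv"].mean())
                summary["donor_clustering_ari"] = clust.agreement
                rng_pct = siv.interindividual_range(
                    state["meth"], state["meth"].tissues[0])
                summary["median_range_pct"] = float(rng_pct.median())
                log(stage, params, t0, n_regions=len(report.summary))
            elif stage == "mqtl":
                _load_inputs(config, state)
                p = config.mqtl
                tissues = p.get("tissues") or [state["meth"].tissues[0]]
                records = []
                for tissue in tissues:
                    rec = mqtl.scan_regions(
                        state["meth"], state["genotypes"], state["regions"],
                        tissue,
                        cis_window=int(p.get("cis_window", 1_000_000)),
                        min_donors=int(p.get("min_donors", 20)),
                        scale=p.get("scale", "beta"),
                    )
                    rec = mqtl.fdr_across_regions(rec,
                                                  alpha=float(p.get("alpha", 0.05)))
                    rec.to_csv(outdir / f"mqtl_{tissue}.tsv", sep="\t",
                               index=False)
                    records.append(rec)
                state["mqtl_records"] = pd.concat(records, ignore_index=True)
                agg = mqtl.effect_aggregation(
                    state["mqtl_records"],
                    p_threshold=float(p.get("p_threshold", 1e-10)),
                )
                summary["mqtl"] = dataclasses.asdict(agg)
                dist = mqtl.simes_snv_distance_distribution(state["mqtl_records"])
                summary["simes_distance"] = dist.to_dict()
                log(stage, dict(p), t0, n_records=len(state["mqtl_records"]))
            elif stage == "haplo":
                _load_inputs(config, state)
                tissue = config.haplo.get("tissue", state["meth"].tissues[0])
                hap = haplotype.haplotype_scan(
                    state["meth"], state["genotypes"], state["regions"],
                    state["blocks"], tissue,
                    min_donors=int(config.haplo.get("min_donors", 20)),
                )
                hap.to_csv(outdir / "haplotype_mqtl.tsv", sep="\t", index=False)
                summary["haplotype_median_r2"] = float(hap["r2_h"].median())
                summary["haplotype_fraction_r_negative"] = float((hap["r"] < 0).mean())
                log(stage, dict(config.haplo), t0, n_records=len(hap))
            elif stage == "methexpr":
                _load_inputs(config, state)
                p = config.methexpr
                target = p.get("target_tissue", "thyroid")
                surrogate = p.get("surrogate_tissue", "blood")
                pairs = pd.DataFrame(
                    [
                        {"region_id": r.region_id, "gene_id": r.gene_id}
                        for r in state["regions"] if r.gene_id
                    ]
                )
                assoc = methexpr.target_tissue_associations(
                    state["meth"], state["expression"], pairs, target,
                    alpha=float(p.get("alpha", 0.05)),
                    min_donors=int(p.get("min_donors", 20)),
                )
                assoc.to_csv(outdir / f"methexpr_{target}.tsv", sep="\t",
                             index=False)
                sig = assoc[assoc["significant"]]
                if len(sig):
                    rec, detail = methexpr.surrogate_recovery(
                        sig, state["meth"], state["expression"], surrogate)
                    detail.to_csv(outdir / f"surrogate_{surrogate}.tsv", sep="\t",
                                  index=False)
                    summary["surrogate_recovery"] = rec.fraction
                    por = methexpr.positional_sign_or(sig, state["regions"])
                    summary["positional_or"] = por.odds_ratio
                    summary["positional_or_p"] = por.p
                log(stage, dict(p), t0, n_pairs=len(assoc),
                    n_significant=int(assoc["significant"].sum()) if len(assoc) else 0)
            elif stage == "enrich":
                _load_inputs(config, state)
                controls = enrichment.matched_controls(
                    state["regions"], state["control_pool"], seed=config.seed)
                io.write_regions(controls, outdir / "matched_controls.bed")
                profile = enrichment.window_enrichment(
                    state["regions"], controls, state["annotations"],
                    max_kb=int(config.enrich.get("max_kb", 50)),
                    alpha=float(config.enrich.get("alpha", 0.05)),
                )
                profile.to_csv(outdir / "enrichment_profile.tsv", sep="\t",
                               index=False)
                summary["enrichment_significant_cells"] = int(
                    profile["significant"].sum())
                log(stage, dict(config.enrich), t0, n_cells=len(profile))
            elif stage == "gwasperm":
                _load_inputs(config, state)
                records = state.get("mqtl_records")
                if records is None:
                    raise RuntimeError("gwasperm requires the mqtl stage")
                sig = records[records.get("significant", False) &
                              records["simes_snv_id"].notna()]
                mqtl_snvs = {
                    rid: sorted(set(grp["simes_snv_id"]))
                    for rid, grp in sig.groupby("region_id")
                }
                results = enrichment.gwas_permutation(
                    mqtl_snvs, state["gwas_catalog"], state["genotypes"],
                    state["regions"],
                    B=int(config.gwasperm.get("B", 1000)), seed=config.seed)
                df = pd.DataFrame(
                    [
                        {"category": r.category, "observed": r.observed_overlap,
                         "null_mean": float(r.null_overlaps.mean()),
                         "fold": r.fold, "p_perm": r.p_perm,
                         "p_bonferroni": r.p_bonferroni}
                        for r in results
                    ]
                )
                df.to_csv(outdir / "gwas_permutation.tsv", sep="\t", index=False)
                summary["gwas_enrichment"] = df.set_index("category")["fold"].to_dict()
                log(stage, dict(config.gwasperm), t0, n_categories=len(df))
            elif stage == "tajima":
                _load_inputs(config, state)
                p = config.tajima
                sets = {}
                for name, rset, maf_range in (
                    ("query", state["regions"],
                     tuple(p.get("maf_range_query", (0.2, 0.5)))),
                    ("control", state.get("matched_controls_for_tajima")
                     or state["control_pool"],
                     tuple(p.get("maf_range_control", (0.02, 0.2)))),
                ):
                    sites = simulate_region_sites(
                        rset, int(p.get("sites_per_region", 8)), maf_range,
                        n_donors=len(state["meth"].donors), seed=config.seed)
                    scan = enrichment.tajimas_d_scan(sites, rset)
                    scan.to_csv(outdir / f"tajima_{name}.tsv", sep="\t",
                                index=False)
                    sets[name] = scan["D"].dropna().tolist()
                comp = enrichment.compare_region_sets(sets)
                comp.to_csv(outdir / "tajima_comparison.tsv", sep="\t",
                            index=False)
                summary["tajima_medians"] = {
                    k: float(np.median(v)) for k, v in sets.items()}
                log(stage, dict(p), t0)
            else:  # pragma: no cover - guarded by config validation
                raise ConfigError(f"unknown stage {stage}")
        except Exception as exc:
            if isinstance(exc, StageFailure):
                raise
            raise StageFailure(stage, exc) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary


def _stage_simulate(config: PipelineConfig, outdir: Path, state: dict) -> None:
    cfg = SimulationConfig(seed=config.seed, **config.simulate)
    regions, pool, cpgs = simulate_regions(cfg)
    gset, blocks = simulate_genotypes(cfg, regions)
    msim = simulate_methylation(cfg, gset, regions)
    esim = simulate_expression(cfg, msim.meth, regions)
    track = simulate_annotations(cfg, regions, pool)
    catalog = simulate_gwas_catalog(
        cfg, gset, msim.truth["causal_snv_id"].tolist(),
        {c: 1.0 for c in GWAS_CATEGORIES})
    fixtures = outdir / "fixtures"
    fixtures.mkdir(exist_ok=True)
    io.write_regions(regions, fixtures / "regions.bed")
    io.write_regions(pool, fixtures / "control_pool.bed")
    io.write_genotypes(gset, fixtures / "genotypes.vcf")
    io.write_haplotype_blocks(blocks, fixtures / "blocks.bed")
    io.write_methylation(msim.meth, fixtures / "methylation.tsv")
    io.write_expression(esim.expr, fixtures / "expression.tsv")
    io.write_annotations(track, fixtures / "annotations.bed")
    io.write_gwas_catalog(catalog, fixtures / "gwas_catalog.tsv")
    msim.truth.to_csv(fixtures / "truth_methylation.tsv", sep="\t", index=False)
    esim.truth.to_csv(fixtures / "truth_expression.tsv", sep="\t", index=False)
    state.update(
        regions=regions, control_pool=pool, cpg_positions=cpgs,
        genotypes=gset, blocks=blocks, meth=msim.meth,
        truth=msim.truth, clamped_fraction=msim.clamped_fraction,
        expression=esim.expr, expression_truth=esim.truth,
        annotations=track, gwas_catalog=catalog,
    )


def _load_inputs(config: PipelineConfig, state: dict) -> None:
    """Fill missing state from input paths (real-data mode)."""
    paths = config.inputs
    if "regions" not in state and "regions" in paths:
        state["regions"] = io.read_regions(paths["regions"], name="query")
    if "control_pool" not in state and "control_pool" in paths:
        state["control_pool"] = io.read_regions(paths["control_pool"],
                                                name="control_pool")
    if "genotypes" not in state and "vcf" in paths:
        state["genotypes"] = io.read_genotypes(paths["vcf"])
    if "meth" not in state and "methylation" in paths:
        state["meth"] = io.read_methylation(paths["methylation"])
    if "expression" not in state and "expression" in paths:
        state["expression"] = io.read_expression(paths["expression"])
    if "annotations" not in state and "annotations" in paths:
        state["annotations"] = io.read_annotations(paths["annotations"])
    if "blocks" not in state and "blocks" in paths:
        state["blocks"] = io.read_haplotype_blocks(paths["blocks"])
    if "gwas_catalog" not in state and "gwas_catalog" in paths:
        state["gwas_catalog"] = io.read_gwas_catalog(paths["gwas_catalog"],
                                                     GWAS_CATEGORIES)
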