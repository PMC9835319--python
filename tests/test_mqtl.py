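"""Simes correction, cis scan, FDR, effect aggregation, concordance."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from corsivkit import mqtl
from corsivkit.types import GenotypeSet, Region, Snv


# ---------------------------------------------------------------------------
# Simes correction


@pytest.mark.parametrize(
    "pvals,expected",
    [
        ([0.01, 0.02, 0.03], 0.03),  # min of (0.03, 0.03, 0.03)
        ([0.04], 0.04),
        ([0.2, 0.2, 0.2, 0.2], 0.2),  # minimum attained at i = n
    ],
)
def test_simes_values(pvals, expected):
    assert mqtl.simes_correct(pvals) == pytest.approx(expected)


def test_simes_rejects_bad_input():
    with pytest.raises(ValueError):
        mqtl.simes_correct([])
    with pytest.raises(ValueError):
        mqtl.simes_correct([0.0, 0.5])
    with pytest.raises(ValueError):
        mqtl.simes_correct([1.5])


@settings(derandomize=True, max_examples=300)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30))
def test_simes_bounds_and_permutation_invariance(pvals):
    adj = mqtl.simes_correct(pvals)
    assert min(pvals) - 1e-12 <= adj <= max(pvals) + 1e-12
    assert adj == pytest.approx(mqtl.simes_correct(list(reversed(sorted(pvals)))))


def test_simes_snv_tie_break_prefers_smallest_raw_p_then_distance():
    scan = pd.DataFrame(
        {
            "snv_id": ["a", "b", "c", "d"],
            "pos": [100, 50, 300, 400],
            "distance": [10, 5, 20, 30],
            "n": [100] * 4,
            "rho": [0.5] * 4,
            "p": [0.01, 0.01, 0.02, 0.04],
            "b": [0.1] * 4,
            "r2": [0.5] * 4,
            "status": ["ok"] * 4,
        }
    )
    # terms: 4*0.01/1=0.04, 4*0.01/2=0.02, 4*0.02/3~=0.0267, 4*0.04/4=0.04
    p_adj, best = mqtl.simes_snv(scan)
    assert p_adj == pytest.approx(0.02)
    assert best["snv_id"] == "b"  # unique minimiser
    # force a tie on the minimising term: equal raw p at ranks 1 and 2
    scan2 = scan.copy()
    scan2.loc[scan2["snv_id"] == "c", "p"] = 0.005
    # sorted p: .005(c), .01, .01, .04 -> terms .02(c), .02, ~.0133?, .04
    p_adj2, best2 = mqtl.simes_snv(scan2)
    assert best2["snv_id"] in {"a", "b", "c"}


# ---------------------------------------------------------------------------
# scan


def toy_genotypes(g_rows, positions, chrom="chr1"):
    snvs = [Snv(f"s{i}", chrom, pos, "A", "G", 0.3)
            for i, pos in enumerate(positions)]
    g = np.asarray(g_rows, dtype=float)
    return GenotypeSet(snvs, [f"d{j}" for j in range(g.shape[1])], g)


def test_scan_monotone_decreasing_gives_rho_minus_one():
    g = np.array([[0, 0, 1, 1, 2, 2] * 5])
    y = 0.8 - 0.1 * g[0]  # monotone decreasing in g, ties matching
    gset = toy_genotypes(g, [150])
    region = Region("chr1", 100, 300, "r")
    scan = mqtl.spearman_scan(y, np.ones(30, bool), gset, region)
    assert scan["rho"].iloc[0] == pytest.approx(-1.0, abs=1e-9)


def test_scan_exact_linear_slope_and_r2():
    g = np.array([[0, 1, 2, 0, 1, 2] * 5])
    y = 0.2 + 0.1 * g[0]
    gset = toy_genotypes(g, [150])
    scan = mqtl.spearman_scan(y, np.ones(30, bool), gset,
                              Region("chr1", 100, 300, "r"))
    assert scan["b"].iloc[0] == pytest.approx(0.1)
    assert scan["r2"].iloc[0] == pytest.approx(1.0)


def test_scan_skips_monomorphic_and_counts_them():
    g = np.array([[1, 1, 1, 1, 1] * 6, [0, 1, 2, 0, 1] * 6])
    y = np.linspace(0.2, 0.8, 30)
    gset = toy_genotypes(g, [150, 200])
    scan = mqtl.spearman_scan(y, np.ones(30, bool), gset,
                              Region("chr1", 100, 300, "r"))
    assert (scan["status"] == "monomorphic").sum() == 1
    assert (scan["status"] == "ok").sum() == 1


def test_scan_distance_convention():
    # SNV at 1-based pos 10500, region [0, 500): distance 10,000 bp
    gset = toy_genotypes(np.array([[0, 1, 2] * 10]), [10500])
    scan = mqtl.spearman_scan(np.linspace(0.2, 0.8, 30), np.ones(30, bool),
                              gset, Region("chr1", 0, 500, "r"))
    assert scan["distance"].iloc[0] == 10000


def test_scan_cis_window_excludes_distal_snvs():
    gset = toy_genotypes(np.array([[0, 1, 2] * 10], ), [2_100_000])
    scan = mqtl.spearman_scan(np.linspace(0.2, 0.8, 30), np.ones(30, bool),
                              gset, Region("chr1", 0, 500, "r"),
                              cis_window=1_000_000)
    assert scan.empty


def test_scan_null_calibration():
    rng = np.random.default_rng(12)
    n, n_snvs = 200, 1000
    g = rng.integers(0, 3, size=(n_snvs, n)).astype(float)
    y = rng.uniform(0.2, 0.8, size=n)
    gset = toy_genotypes(g, list(range(1000, 1000 + n_snvs)))
    scan = mqtl.spearman_scan(y, np.ones(n, bool), gset,
                              Region("chr1", 0, 2000, "r"))
    frac = (scan["p"] < 0.05).mean()
    assert frac == pytest.approx(0.05, abs=0.02)


# ---------------------------------------------------------------------------
# FDR across regions


def test_bh_examples():
    rec = pd.DataFrame(
        {"region_id": [f"r{i}" for i in range(100)],
         "simes_p_adjusted": [0.001] * 10 + [0.9] * 90}
    )
    out = mqtl.fdr_across_regions(rec)
    assert out["significant"].sum() == 10
    assert set(out[out["significant"]]["region_id"]) == {f"r{i}" for i in range(10)}

    allone = pd.DataFrame({"region_id": ["a", "b"], "simes_p_adjusted": [1.0, 1.0]})
    assert not mqtl.fdr_across_regions(allone)["significant"].any()

    single = pd.DataFrame({"region_id": ["a"], "simes_p_adjusted": [0.04]})
    out = mqtl.fdr_across_regions(single)
    assert out["fdr_q"].iloc[0] == pytest.approx(0.04)
    assert out["significant"].iloc[0]


# ---------------------------------------------------------------------------
# aggregation and bookkeeping


def test_effect_aggregation_arithmetic():
    rec = pd.DataFrame(
        {
            "simes_snv_raw_p": [1e-12] * 3,
            "delta_x_r2": [0.1, 0.2, 0.3],
            "r2": [0.5, 0.6, 0.7],
            "b": [-0.1, -0.2, 0.3],
        }
    )
    agg = mqtl.effect_aggregation(rec)
    assert agg.median_delta_x_r2 == pytest.approx(0.2)
    assert agg.sum_delta_x_r2 == pytest.approx(0.6)
    assert agg.fraction_b_negative == pytest.approx(2 / 3)


def test_effect_aggregation_empty_after_threshold():
    rec = pd.DataFrame({"simes_snv_raw_p": [0.5], "delta_x_r2": [0.1],
                        "r2": [0.5], "b": [0.1]})
    agg = mqtl.effect_aggregation(rec)
    assert agg.n_records == 0 and np.isnan(agg.median_r2)


def test_m_and_beta_modes_agree_on_sign(small_cohort):
    beta_rec = mqtl.scan_regions(small_cohort.meth, small_cohort.genotypes,
                                 small_cohort.regions, "blood", scale="beta")
    m_rec = mqtl.scan_regions(small_cohort.meth, small_cohort.genotypes,
                              small_cohort.regions, "blood", scale="M")
    merged = beta_rec.merge(m_rec, on="region_id", suffixes=("_b", "_m"))
    assert (np.sign(merged["b_b"]) == np.sign(merged["b_m"])).all()


def test_distance_distribution(recovery_records):
    dist = mqtl.simes_snv_distance_distribution(recovery_records)
    assert 0 <= dist["within_1kb"] <= dist["within_10kb"] <= dist["within_1000kb"] <= 1


# ---------------------------------------------------------------------------
# cross-tissue concordance


def concordance_input(snv_ids, tissues):
    return pd.DataFrame(
        {
            "region_id": ["r1"] * len(tissues),
            "tissue": tissues,
            "simes_snv_id": snv_ids,
            "significant": [True] * len(tissues),
        }
    )


def test_concordance_identical_snv(small_cohort):
    tissues = [f"t{i}" for i in range(6)]
    sid = small_cohort.genotypes.snvs[0].snv_id
    out = mqtl.cross_tissue_concordance(
        concordance_input([sid] * 6, tissues), small_cohort.genotypes,
        small_cohort.blocks)
    assert out.iloc[0]["n_tissues_same_snv"] == 6
    assert out.iloc[0]["n_tissues_same_block"] == 6


def test_concordance_same_block_different_snvs(small_cohort):
    block = next(b for b in small_cohort.blocks if len(b.snv_ids) >= 2)
    ids = list(block.snv_ids[:2]) * 3
    out = mqtl.cross_tissue_concordance(
        concordance_input(ids, [f"t{i}" for i in range(6)]),
        small_cohort.genotypes, small_cohort.blocks)
    assert out.iloc[0]["n_tissues_same_snv"] == 3
    assert out.iloc[0]["n_tissues_same_block"] == 6


def test_concordance_block_never_below_snv(small_cohort, recovery_cohort):
    tissues = ["blood", "thyroid", "lung"]
    recs = []
    for t in tissues:
        r = mqtl.scan_regions(small_cohort.meth, small_cohort.genotypes,
                              small_cohort.regions, t)
        recs.append(mqtl.fdr_across_regions(r))
    out = mqtl.cross_tissue_concordance(pd.concat(recs), small_cohort.genotypes,
                                        small_cohort.blocks)
    assert (out["n_tissues_same_block"] >= out["n_tissues_same_snv"]).all()


# ---------------------------------------------------------------------------
# SNV-CpG overlap robustness


def test_overlap_classification(small_cohort, recovery_records):
    cohort = small_cohort
    rec = mqtl.scan_regions(cohort.meth, cohort.genotypes, cohort.regions, "blood")
    # no CpGs at any SNV position -> everything in the no-overlap stratum
    empty_cpgs = {r.region_id: np.array([], dtype=int) for r in cohort.regions}
    out = mqtl.snv_cpg_overlap_robustness(rec, cohort.genotypes, cohort.regions,
                                          empty_cpgs)
    assert set(out["stratum"]) == {"no_overlap"}
    # plant a CpG exactly at an in-region SNV position -> overlapping
    region = cohort.regions.regions[0]
    inside = next(s for s in cohort.genotypes.snvs
                  if s.chrom == region.chrom
                  and region.start <= s.pos0 < region.end)
    planted = dict(empty_cpgs)
    planted[region.region_id] = np.array([inside.pos0])
    out2 = mqtl.snv_cpg_overlap_robustness(rec, cohort.genotypes, cohort.regions,
                                           planted)
    over = out2[out2["stratum"] == "overlapping"]
    assert len(over) == 1 and over["n_regions"].iloc[0] == 1


def test_overlap_strata_indistinguishable_when_effects_are_distal(recovery_cohort,
                                                                  recovery_records):
    out = mqtl.snv_cpg_overlap_robustness(
        recovery_records, recovery_cohort.genotypes, recovery_cohort.regions,
        recovery_cohort.cpg_positions)
    if len(out) == 2:  # both strata present
        assert out.attrs["p_r2"] > 0.001  # no artefactual difference
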