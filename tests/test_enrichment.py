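"""Matched controls, window enrichment, permutation tests, Tajima's D."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from corsivkit import enrichment
from corsivkit.simulate import SimulationConfig, simulate_region_sites
from corsivkit.types import (
    AnnotationTrack,
    GenotypeSet,
    GwasCatalog,
    Region,
    RegionSet,
    Snv,
)


# ---------------------------------------------------------------------------
# window geometry


def test_flank_window_arithmetic():
    region = Region("chr1", 10000, 10200, "r")
    left, right = enrichment.flank_windows(region, 3)
    assert left == (7000, 8000)
    assert right == (12200, 13200)


def test_flank_window_adjacent_offset():
    region = Region("chr1", 10000, 10200, "r")
    left, right = enrichment.flank_windows(region, 1)
    assert left == (9000, 10000)       # abuts the region start
    assert right == (10200, 11200)     # abuts the region end


# ---------------------------------------------------------------------------
# matched controls


def grid_regions(name, n, chrom="chr1", start0=100_000, spacing=10_000,
                 length=200, cpg=10, prefix="q"):
    return RegionSet(
        name,
        [Region(chrom, start0 + i * spacing, start0 + i * spacing + length,
                f"{prefix}{i}", cpg) for i in range(n)],
    )


def test_exact_duplicate_pool_matches_everything():
    query = grid_regions("q", 20)
    pool = grid_regions("p", 20, start0=600_000, prefix="c")
    out = enrichment.matched_controls(query, pool, seed=1)
    assert len(out) == 20


def test_empty_pool_raises():
    query = grid_regions("q", 5)
    with pytest.raises(ValueError):
        enrichment.matched_controls(query, RegionSet("p", []), seed=1)


def test_matched_controls_deterministic():
    query = grid_regions("q", 10)
    pool = RegionSet(
        "p",
        [Region("chr1", 600_000 + i * 1000, 600_000 + i * 1000 + 200, f"c{i}", 10)
         for i in range(40)],
    )
    a = enrichment.matched_controls(query, pool, seed=9)
    b = enrichment.matched_controls(query, pool, seed=9)
    assert [r.region_id for r in a] == [r.region_id for r in b]


def test_unmatchable_queries_error():
    query = grid_regions("q", 10, length=200)
    pool = grid_regions("p", 10, start0=600_000, length=5000, prefix="c")
    with pytest.raises(ValueError, match="matched only"):
        enrichment.matched_controls(query, pool, seed=1)


def test_pool_overlap_with_query_rejected():
    query = grid_regions("q", 3)
    with pytest.raises(ValueError, match="disjoint"):
        enrichment.matched_controls(query, query, seed=1)


# ---------------------------------------------------------------------------
# window enrichment


def test_identical_geometry_gives_or_one():
    query = grid_regions("q", 10, spacing=200_000)
    reference = RegionSet(
        "ref",
        [Region(r.chrom, r.start + 100_000, r.end + 100_000, f"ref_{r.region_id}",
                r.cpg_count) for r in query],
    )
    # one element at the same offset from every region in both sets
    rows = []
    for rset in (query, reference):
        for r in rset:
            rows.append((r.chrom, r.end + 2500, r.end + 2600, "LINE1", "L1PA2"))
    track = AnnotationTrack(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "cls", "subclass"]))
    profile = enrichment.window_enrichment(query, reference, track, max_kb=5)
    assert np.allclose(profile["odds_ratio"], 1.0)
    assert not profile["significant"].any()


def test_missing_class_is_skipped():
    query = grid_regions("q", 5, spacing=200_000)
    reference = grid_regions("ref", 5, start0=5_000_000, spacing=200_000,
                             prefix="c")
    rows = [(r.chrom, r.end + 500, r.end + 600, "LINE1", "L1") for r in query]
    track = AnnotationTrack(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "cls", "subclass"]))
    profile = enrichment.window_enrichment(query, reference, track, max_kb=3,
                                           classes=["LINE1", "LTR"])
    assert set(profile["cls"]) == {"LINE1"}


# ---------------------------------------------------------------------------
# GWAS permutation


@pytest.fixture(scope="module")
def perm_setup():
    cfg = SimulationConfig(n_donors=40, n_regions=30, n_tissues=2,
                           snvs_per_region_window=30, seed=23)
    from corsivkit.simulate import simulate_genotypes, simulate_methylation, simulate_regions

    regions, _, _ = simulate_regions(cfg)
    gset, _ = simulate_genotypes(cfg, regions)
    truth = simulate_methylation(cfg, gset, regions).truth
    mqtl_snvs = {row.region_id: [row.causal_snv_id] for row in truth.itertuples()}
    return cfg, regions, gset, truth, mqtl_snvs


def catalog_from_ids(gset, ids, category="metabolic"):
    idx = [gset.index_of(i) for i in ids]
    df = pd.DataFrame(
        {
            "chrom": [gset.snvs[i].chrom for i in idx],
            "pos": [gset.snvs[i].pos for i in idx],
            "snv_id": [gset.snvs[i].snv_id for i in idx],
            "category": category,
        }
    )
    return GwasCatalog(df, (category,))


def test_catalog_equal_to_mqtl_set_is_maximal(perm_setup):
    cfg, regions, gset, truth, mqtl_snvs = perm_setup
    catalog = catalog_from_ids(gset, truth["causal_snv_id"])
    res = enrichment.gwas_permutation(mqtl_snvs, catalog, gset, regions,
                                      B=200, seed=3)[0]
    assert res.observed_overlap == len(truth)
    assert res.p_perm == pytest.approx(1 / 201)
    assert res.fold > 5


def test_permutation_deterministic(perm_setup):
    cfg, regions, gset, truth, mqtl_snvs = perm_setup
    catalog = catalog_from_ids(gset, gset.snv_ids[::7])
    a = enrichment.gwas_permutation(mqtl_snvs, catalog, gset, regions, B=100,
                                    seed=5)[0]
    b = enrichment.gwas_permutation(mqtl_snvs, catalog, gset, regions, B=100,
                                    seed=5)[0]
    assert np.array_equal(a.null_overlaps, b.null_overlaps)
    assert a.p_perm == b.p_perm


def test_permutation_rejects_small_b(perm_setup):
    cfg, regions, gset, truth, mqtl_snvs = perm_setup
    catalog = catalog_from_ids(gset, gset.snv_ids[::7])
    with pytest.raises(ValueError, match="B"):
        enrichment.gwas_permutation(mqtl_snvs, catalog, gset, regions, B=50)


def test_null_mean_scales_with_category_size(perm_setup):
    cfg, regions, gset, truth, mqtl_snvs = perm_setup
    small = catalog_from_ids(gset, gset.snv_ids[::10])
    large = catalog_from_ids(gset, gset.snv_ids[::5])
    rs = enrichment.gwas_permutation(mqtl_snvs, small, gset, regions, B=400,
                                     seed=7)[0]
    rl = enrichment.gwas_permutation(mqtl_snvs, large, gset, regions, B=400,
                                     seed=7)[0]
    ratio = rl.null_overlaps.mean() / rs.null_overlaps.mean()
    assert ratio == pytest.approx(2.0, rel=0.2)


# ---------------------------------------------------------------------------
# eQTL bootstrap


def test_lookup_equals_background_gives_fold_one():
    bg = [f"s{i}" for i in range(100)]
    res = enrichment.eqtl_bootstrap(bg[:10], bg, bg, B=200, seed=1)
    assert res.fold == pytest.approx(1.0)
    assert res.ci_low == pytest.approx(1.0)


def test_bootstrap_expected_fold_two():
    bg = [f"s{i}" for i in range(2000)]
    lookup = bg[:1000]  # background 50% in lookup
    query = bg[:50]     # query all in lookup
    res = enrichment.eqtl_bootstrap(query, lookup, bg, B=500, seed=2)
    assert res.fold == pytest.approx(2.0, rel=0.05)


def test_bootstrap_requires_background_superset():
    with pytest.raises(ValueError):
        enrichment.eqtl_bootstrap(["x"], ["a"], ["a", "b"], B=200)


def test_bootstrap_deterministic():
    bg = [f"s{i}" for i in range(500)]
    a = enrichment.eqtl_bootstrap(bg[:20], bg[:100], bg, B=300, seed=9)
    b = enrichment.eqtl_bootstrap(bg[:20], bg[:100], bg, B=300, seed=9)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


# ---------------------------------------------------------------------------
# Tajima's D


def hap_gset(haps, chrom="chr1", positions=None):
    """Explicit haplotypes: array (n_sites, n_donors, 2)."""
    haps = np.asarray(haps, dtype=int)
    n_sites, n_donors, _ = haps.shape
    positions = positions or [10 + i for i in range(n_sites)]
    snvs = [Snv(f"s{i}", chrom, positions[i], "A", "G", 0.2)
            for i in range(n_sites)]
    return GenotypeSet(snvs, [f"d{j}" for j in range(n_donors)],
                       haps.sum(axis=2).astype(float), haps)


def test_monomorphic_region_has_no_d():
    gset = hap_gset(np.zeros((3, 5, 2)))
    res = enrichment.tajimas_d(gset, Region("chr1", 0, 100, "r"))
    assert res.S == 0 and math.isnan(res.D)


def test_tajima_hand_computed_single_site():
    # n = 4 chromosomes, one site with minor count k = 2
    haps = np.array([[[1, 0], [1, 0]]])  # 2 donors -> 4 chromosomes, k = 2
    gset = hap_gset(haps)
    res = enrichment.tajimas_d(gset, Region("chr1", 0, 100, "r"))
    assert res.n_chromosomes == 4
    assert res.S == 1
    # 4 of the C(4,2) = 6 chromosome pairs differ at the site: pi = 2/3
    assert res.pi == pytest.approx(2 * 2 * 2 / (4 * 3))
    a1 = 1 + 1 / 2 + 1 / 3
    assert res.pi - res.S / a1 == pytest.approx(2 / 3 - 6 / 11)
    # full D against an independent evaluation of the standard constants
    n = 4
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    expected = (2 / 3 - 1 / a1) / math.sqrt(e1 * 1)
    assert res.D == pytest.approx(expected, abs=1e-12)


def test_tajima_requires_four_chromosomes():
    gset = hap_gset(np.array([[[1, 0]]]))  # single donor
    with pytest.raises(ValueError, match="chromosomes"):
        enrichment.tajimas_d(gset, Region("chr1", 0, 100, "r"))


def brute_force_pi_and_d(haps_in_region: np.ndarray) -> tuple[float, float]:
    """Independent oracle: enumerate all chromosome pairs."""
    n_sites, n_donors, _ = haps_in_region.shape
    chroms = haps_in_region.reshape(n_sites, n_donors * 2).T  # (n, sites)
    n = chroms.shape[0]
    segregating = [j for j in range(n_sites)
                   if 0 < chroms[:, j].sum() < n]
    S = len(segregating)
    total = 0
    for x, y in itertools.combinations(range(n), 2):
        total += int((chroms[x, segregating] != chroms[y, segregating]).sum())
    n_pairs = n * (n - 1) // 2
    pi = total / n_pairs
    if S == 0:
        return pi, math.nan
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return pi, (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def test_tajima_agrees_with_brute_force_on_random_fixtures():
    rng = np.random.default_rng(33)
    region = Region("chr1", 0, 1000, "r")
    for trial in range(12):
        n_donors = int(rng.integers(2, 7))      # 4..12 chromosomes
        n_sites = int(rng.integers(1, 21))      # <= 20 sites
        haps = (rng.random((n_sites, n_donors, 2)) < rng.uniform(0.05, 0.6)
                ).astype(int)
        gset = hap_gset(haps, positions=list(rng.choice(np.arange(1, 1001),
                                                        n_sites, replace=False)))
        res = enrichment.tajimas_d(gset, region)
        pi_b, d_b = brute_force_pi_and_d(haps)
        assert res.pi == pytest.approx(pi_b, abs=1e-12)
        if math.isnan(d_b):
            assert math.isnan(res.D)
        else:
            assert res.D == pytest.approx(d_b, abs=1e-12)


# ---------------------------------------------------------------------------
# set comparison


def test_compare_region_sets_detects_shift():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, 100)
    out = enrichment.compare_region_sets({"a": a, "b": a + 1.0})
    assert out["p"].iloc[0] < 1e-6


def test_compare_region_sets_excludes_small_sets():
    rng = np.random.default_rng(2)
    with pytest.raises(ValueError):
        enrichment.compare_region_sets({"a": rng.normal(size=100),
                                        "tiny": [1, 2, 3, 4, 5]})
    out = enrichment.compare_region_sets(
        {"a": rng.normal(size=100), "b": rng.normal(size=100),
         "tiny": [1, 2, 3, 4, 5]})
    assert {"a", "b"} == set(out["set_a"]) | set(out["set_b"])
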