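"""Methylation-expression association, surrogate recovery, positional OR."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from corsivkit import methexpr
from corsivkit.types import MethylationTensor, Region, RegionSet


def tensor(values):
    values = np.asarray(values, dtype=float)
    r, d, t = values.shape
    return MethylationTensor(
        [f"r{i}" for i in range(r)], [f"d{i}" for i in range(d)],
        ["target", "surrogate"][:t] if t <= 2 else [f"t{i}" for i in range(t)],
        values, np.ones_like(values, dtype=bool),
    )


def expr_frame(gene, donors, tissue, values):
    return pd.DataFrame({"gene_id": gene, "donor_id": donors, "tissue": tissue,
                         "value": values})


def test_expression_filter_examples():
    donors = [f"d{i}" for i in range(4)]
    frames = []
    # geneA: median 2.0 in 5 tissues; geneB: all zero; geneC: only 4 tissues
    for t in range(5):
        frames.append(expr_frame("geneA", donors, f"t{t}", [2.0] * 4))
        frames.append(expr_frame("geneB", donors, f"t{t}", [0.0] * 4))
    for t in range(4):
        frames.append(expr_frame("geneC", donors, f"t{t}", [1.0] * 4))
    expr = pd.concat(frames, ignore_index=True)
    kept = methexpr.expression_filter(expr, [f"t{i}" for i in range(5)],
                                      min_level=1.0, min_tissues=5)
    assert kept == ["geneA"]


def test_exact_negative_association_is_significant():
    m = np.linspace(0.2, 0.8, 30)
    meth = tensor(m.reshape(1, 30, 1))
    expr = expr_frame("g0", meth.donors, "target", 3 - 2 * m)
    pairs = pd.DataFrame({"region_id": ["r0"], "gene_id": ["g0"]})
    out = methexpr.target_tissue_associations(meth, expr, pairs, "target")
    assert out["r"].iloc[0] == pytest.approx(-1.0)
    assert out["significant"].iloc[0]


def test_too_few_donors_skips_pair():
    m = np.linspace(0.2, 0.8, 5)
    meth = tensor(m.reshape(1, 5, 1))
    expr = expr_frame("g0", meth.donors, "target", 3 - 2 * m)
    pairs = pd.DataFrame({"region_id": ["r0"], "gene_id": ["g0"]})
    out = methexpr.target_tissue_associations(meth, expr, pairs, "target",
                                              min_donors=20)
    assert out.empty


def test_constant_expression_skipped():
    m = np.linspace(0.2, 0.8, 30)
    meth = tensor(m.reshape(1, 30, 1))
    expr = expr_frame("g0", meth.donors, "target", [5.0] * 30)
    pairs = pd.DataFrame({"region_id": ["r0"], "gene_id": ["g0"]})
    out = methexpr.target_tissue_associations(meth, expr, pairs, "target")
    assert out.empty


def make_significant(meth, expr):
    pairs = pd.DataFrame({"region_id": ["r0"], "gene_id": ["g0"]})
    out = methexpr.target_tissue_associations(meth, expr, pairs, "target")
    return out[out["significant"]]


def test_surrogate_identical_methylation_recovers_everything():
    m = np.linspace(0.2, 0.8, 40)
    meth = tensor(np.stack([m, m], axis=1).reshape(1, 40, 2))
    expr = expr_frame("g0", meth.donors, "target", 3 - 2 * m)
    sig = make_significant(meth, expr)
    rec, detail = methexpr.surrogate_recovery(sig, meth, expr, "surrogate")
    assert rec.fraction == 1.0
    assert detail["recovered"].all()


def test_surrogate_noise_fails_to_recover():
    rng = np.random.default_rng(5)
    m = np.linspace(0.2, 0.8, 40)
    noise = rng.uniform(0.2, 0.8, 40)
    meth = tensor(np.stack([m, noise], axis=1).reshape(1, 40, 2))
    expr = expr_frame("g0", meth.donors, "target", 3 - 2 * m)
    sig = make_significant(meth, expr)
    rec, _ = methexpr.surrogate_recovery(sig, meth, expr, "surrogate")
    assert rec.fraction == 0.0


def test_surrogate_empty_significant_set_raises():
    meth = tensor(np.linspace(0.2, 0.8, 30).reshape(1, 30, 1))
    with pytest.raises(ValueError):
        methexpr.surrogate_recovery(pd.DataFrame(), meth, pd.DataFrame(), "t")


# ---------------------------------------------------------------------------
# positional odds ratio


def or_input(a, b, c, d):
    """a/b: near-end negative/positive; c/d: body negative/positive."""
    rows = []
    regions = []
    i = 0
    for count, pos_cls, sign in (
        (a, "within_3kb_of_end", -1), (b, "within_3kb_of_end", 1),
        (c, "gene_body", -1), (d, "gene_body", 1),
    ):
        for _ in range(count):
            rid = f"r{i}"
            regions.append(Region("chr1", 100 * i + 10, 100 * i + 50, rid, 5,
                                  f"g{i}", pos_cls))
            rows.append({"region_id": rid, "gene_id": f"g{i}", "r": 0.5 * sign})
            i += 1
    return pd.DataFrame(rows), RegionSet("t", regions)


def test_positional_or_value():
    sig, regions = or_input(30, 10, 15, 20)
    res = methexpr.positional_sign_or(sig, regions)
    assert res.odds_ratio == pytest.approx(4.0)
    assert not res.haldane_corrected


def test_positional_or_balanced_is_one():
    sig, regions = or_input(10, 10, 7, 7)
    assert methexpr.positional_sign_or(sig, regions).odds_ratio == pytest.approx(1.0)


def test_positional_or_fisher_two_by_two():
    # table [[2, 0], [0, 2]]: two-sided Fisher p = 1/3
    sig, regions = or_input(2, 0, 0, 2)
    res = methexpr.positional_sign_or(sig, regions)
    assert res.p == pytest.approx(1 / 3)
    assert res.haldane_corrected  # zero cells -> Haldane OR


def test_positional_or_missing_class_raises():
    sig, regions = or_input(5, 5, 0, 0)
    with pytest.raises(ValueError, match="gene_body"):
        methexpr.positional_sign_or(sig, regions)


def test_positional_or_invariant_to_double_swap():
    sig, regions = or_input(12, 5, 7, 9)
    res = methexpr.positional_sign_or(sig, regions)
    # swap both row labels (position classes) and column labels (signs)
    swapped_regions = RegionSet(
        "t",
        [
            Region(r.chrom, r.start, r.end, r.region_id, r.cpg_count, r.gene_id,
                   "gene_body" if r.gene_position_class == "within_3kb_of_end"
                   else "within_3kb_of_end")
            for r in regions
        ],
    )
    swapped_sig = sig.copy()
    swapped_sig["r"] = -swapped_sig["r"]
    res2 = methexpr.positional_sign_or(swapped_sig, swapped_regions)
    assert res2.odds_ratio == pytest.approx(res.odds_ratio)
    assert res2.p == pytest.approx(res.p)
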