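"""Methylation-expression association and surrogate-tissue inference.

In a target tissue (one that cannot be sampled non-invasively), gene
expression is tested for association with region methylation. For the
significant pairs, the question with practical value is whether methylation
measured in an accessible surrogate tissue (blood, skin) recovers the same
association with target-tissue expression — which it should, to the extent
the methylation variation is systemic. A positional odds ratio then asks
whether regions near a gene end are biased toward negative
methylation-expression correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import RegionSet


def expression_filter(
    expr: pd.DataFrame,
    tissues: list[str],
    min_level: float = 1.0,
    min_tissues: int = 5,
) -> list[str]:
    """Genes whose median expression reaches ``min_level`` in enough tissues."""
    med = (
        expr[expr["tissue"].isin(tissues)]
        .groupby(["gene_id", "tissue"])["value"]
        .median()
        .unstack()
    )
    ok = (med >= min_level).sum(axis=1) >= min_tissues
    return sorted(ok[ok].index)


def _expr_lookup(expr: pd.DataFrame, tissue: str) -> dict[str, pd.Series]:
    sub = expr[expr["tissue"] == tissue]
    return {g: grp.set_index("donor_id")["value"] for g, grp in sub.groupby("gene_id")}


def target_tissue_associations(
    meth,
    expr: pd.DataFrame,
    pairs: pd.DataFrame,  # columns region_id, gene_id
    target_tissue: str,
    alpha: float = 0.05,
    min_donors: int = 20,
) -> pd.DataFrame:
    """Spearman correlation per region-gene pair in the target tissue.

    BH FDR within the tissue; significant iff q < alpha. Pairs with constant
    expression or too few donors carry both measurements are skipped.
    """
    k = meth.tissue_index(target_tissue)
    lookup = _expr_lookup(expr, target_tissue)
    rows = []
    for pair in pairs.itertuples():
        if pair.gene_id not in lookup:
            continue
        e = lookup[pair.gene_id]
        i = meth.region_index(pair.region_id)
        donors = [d for j, d in enumerate(meth.donors)
                  if meth.mask[i, j, k] and d in e.index]
        if len(donors) < min_donors:
            continue
        didx = [meth.donors.index(d) for d in donors]
        m = meth.values[i, didx, k]
        ev = e.loc[donors].to_numpy()
        if np.std(ev) == 0 or np.std(m) == 0:
            continue
        res = stats.spearmanr(m, ev)
        rows.append(
            {
                "region_id": pair.region_id,
                "gene_id": pair.gene_id,
                "target_tissue": target_tissue,
                "r": float(res.statistic),
                "p": float(res.pvalue),
                "n_donors": len(donors),
            }
        )
    out = pd.DataFrame(rows, columns=["region_id", "gene_id", "target_tissue",
                                      "r", "p", "n_donors"])
    if len(out):
        _, q, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
        out["q"] = q
        out["significant"] = q < alpha
        out["direction"] = np.sign(out["r"]).astype(int)
    else:
        out["q"] = out["significant"] = out["direction"] = pd.Series(dtype=float)
    return out


@dataclass
class SurrogateRecovery:
    surrogate_tissue: str
    n_pairs: int
    n_excluded: int
    n_recovered: int

    @property
    def fraction(self) -> float:
        return self.n_recovered / self.n_pairs if self.n_pairs else np.nan


def surrogate_recovery(
    significant: pd.DataFrame,
    meth,
    expr: pd.DataFrame,
    surrogate_tissue: str,
    nominal_alpha: float = 0.05,
    min_donors: int = 20,
) -> tuple[SurrogateRecovery, pd.DataFrame]:
    """Re-test significant pairs with surrogate-tissue methylation.

    For each target-tissue-significant pair, the surrogate tissue's
    methylation is correlated against the TARGET tissue's expression; the
    pair is recovered iff nominal p < alpha with the same correlation sign.
    Pairs lacking surrogate methylation are excluded from the denominator
    (counted).
    """
    if significant.empty:
        raise ValueError("target-tissue significant set is empty")
    ks = meth.tissue_index(surrogate_tissue)
    rows = []
    n_excluded = 0
    for pair in significant.itertuples():
        lookup = _expr_lookup(expr[expr["gene_id"] == pair.gene_id],
                              pair.target_tissue)
        e = lookup.get(pair.gene_id)
        i = meth.region_index(pair.region_id)
        donors = [d for j, d in enumerate(meth.donors)
                  if meth.mask[i, j, ks] and e is not None and d in e.index]
        if e is None or len(donors) < min_donors:
            n_excluded += 1
            continue
        didx = [meth.donors.index(d) for d in donors]
        m = meth.values[i, didx, ks]
        ev = e.loc[donors].to_numpy()
        if np.std(m) == 0 or np.std(ev) == 0:
            n_excluded += 1
            continue
        res = stats.spearmanr(m, ev)
        r_s, p_s = float(res.statistic), float(res.pvalue)
        recovered = p_s < nominal_alpha and np.sign(r_s) == np.sign(pair.r)
        rows.append(
            {
                "region_id": pair.region_id,
                "gene_id": pair.gene_id,
                "surrogate_tissue": surrogate_tissue,
                "r_s": r_s,
                "p_s": p_s,
                "recovered": bool(recovered),
            }
        )
    detail = pd.DataFrame(rows, columns=["region_id", "gene_id",
                                         "surrogate_tissue", "r_s", "p_s",
                                         "recovered"])
    summary = SurrogateRecovery(
        surrogate_tissue, len(detail), n_excluded, int(detail["recovered"].sum())
        if len(detail) else 0,
    )
    return summary, detail


@dataclass
class PositionalOr:
    odds_ratio: float
    p: float
    table: np.ndarray  # rows: within_3kb_of_end, gene_body; cols: negative, positive
    haldane_corrected: bool


def positional_sign_or(
    significant: pd.DataFrame, regions: RegionSet
) -> PositionalOr:
    """Odds ratio for negative correlation near gene ends vs gene bodies.

    2x2 table of (within_3kb_of_end vs gene_body) x (negative vs positive
    correlation) over significant pairs; OR = ad/bc with the Haldane 0.5
    correction on any zero cell (flagged), two-sided Fisher exact p on the
    uncorrected counts.
    """
    cls = {r.region_id: r.gene_position_class for r in regions}
    sub = significant.copy()
    sub["position"] = sub["region_id"].map(cls)
    sub = sub[sub["position"].isin(["within_3kb_of_end", "gene_body"])]
    for pos in ("within_3kb_of_end", "gene_body"):
        if not (sub["position"] == pos).any():
            raise ValueError(f"no significant pairs in position class {pos!r}")
    a = int(((sub["position"] == "within_3kb_of_end") & (sub["r"] < 0)).sum())
    b = int(((sub["position"] == "within_3kb_of_end") & (sub["r"] > 0)).sum())
    c = int(((sub["position"] == "gene_body") & (sub["r"] < 0)).sum())
    d = int(((sub["position"] == "gene_body") & (sub["r"] > 0)).sum())
    table = np.array([[a, b], [c, d]], dtype=float)
    corrected = bool((table == 0).any())
    t = table + 0.5 if corrected else table
    odds = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    p = float(stats.fisher_exact(table.astype(int), alternative="two-sided")[1])
    return PositionalOr(odds, p, table.astype(int), corrected)
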