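"""Anchor-centered coexpression ranking, cofactor rewiring, preranked ES.

Genes are ranked by the absolute Pearson correlation of their expression
with an anchor gene.  For a panel of cofactors the correlation is computed
separately within two strata; the difference Δr = r_high − r_low is tested
with Fisher's r-to-z transformation,

    z = (atanh r_high − atanh r_low) / sqrt(1/(n_high−3) + 1/(n_low−3)),

with two-sided normal p-values and BH correction across the panel.  A
preranked running-enrichment statistic (GSEA-style weighted Kolmogorov–
Smirnov walk) scores the concentration of a gene set near the top of the
ranking, with significance from random same-size gene-set permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .utils import ConfigError, InputError, bh_adjust

__all__ = ["rank_by_correlation", "delta_r_test", "preranked_enrichment",
           "EnrichmentScoreResult", "running_enrichment_curve"]


def rank_by_correlation(expr: pd.DataFrame, anchor: str) -> pd.DataFrame:
    """Pearson correlation of every gene with the anchor, ranked by |r|.

    The anchor itself is excluded; zero-variance genes are excluded with a
    warning.  Ties in |r| are broken lexicographically by gene id.
    """
    if anchor not in expr.index:
        raise InputError(f"anchor gene {anchor!r} absent from matrix")
    if expr.shape[1] < 4:
        raise InputError("need at least 4 samples")
    x = expr.loc[anchor].to_numpy(float)
    rest = expr.drop(index=anchor)
    mat = rest.to_numpy(float)
    sd = mat.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} zero-variance gene(s) excluded")
    mat = mat[keep]
    xc = x - x.mean()
    mc = mat - mat.mean(axis=1, keepdims=True)
    r = (mc @ xc) / (np.sqrt((mc ** 2).sum(axis=1)) * np.sqrt((xc ** 2).sum()))
    out = pd.DataFrame({"gene": rest.index[keep], "r": r, "abs_r": np.abs(r)})
    out = out.sort_values(["abs_r", "gene"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if len(a) < 4:
        raise InputError("fewer than 4 complete observations")
    return float(np.corrcoef(a, b)[0, 1]), int(len(a))


def delta_r_test(expr: pd.DataFrame, anchor: str, panel, strata: pd.Series) -> pd.DataFrame:
    """Stratum-specific anchor correlations and Fisher r-to-z rewiring test.

    Returns one record per cofactor with r_high, r_low, Δr, the z statistic,
    two-sided p and BH q over the panel.  Cofactors with |r| = 1 in a
    stratum are flagged degenerate with missing p (the transform diverges).
    """
    if anchor not in expr.index:
        raise InputError(f"anchor gene {anchor!r} absent from matrix")
    s = strata.reindex(expr.columns)
    cols = {grp: s.index[s == grp] for grp in ("high", "low")}
    rows = []
    for cof in panel:
        if cof not in expr.index:
            raise InputError(f"cofactor {cof!r} absent from matrix")
        rec = {"cofactor": cof, "degenerate": False}
        for grp in ("high", "low"):
            a = expr.loc[anchor, cols[grp]].to_numpy(float)
            b = expr.loc[cof, cols[grp]].to_numpy(float)
            rec[f"r_{grp}"], rec[f"n_{grp}"] = _pearson(a, b)
        rec["delta_r"] = rec["r_high"] - rec["r_low"]
        if abs(rec["r_high"]) >= 1 or abs(rec["r_low"]) >= 1:
            rec.update(degenerate=True, z_stat=np.nan, p_value=np.nan)
        else:
            se = np.sqrt(1 / (rec["n_high"] - 3) + 1 / (rec["n_low"] - 3))
            z = (np.arctanh(rec["r_high"]) - np.arctanh(rec["r_low"])) / se
            rec["z_stat"] = float(z)
            rec["p_value"] = float(2 * stats.norm.sf(abs(z)))
        rows.append(rec)
    res = pd.DataFrame(rows)
    res["q_value"] = bh_adjust(res["p_value"])
    return res


@dataclass
class EnrichmentScoreResult:
    es: float
    nominal_p: float
    n_perm: int
    seed: int
    n_set_effective: int
    untestable: bool = False


def running_enrichment_curve(is_member: np.ndarray, scores: np.ndarray,
                             weight_exponent: float = 1.0) -> np.ndarray:
    """Running sum of the weighted KS walk along a ranked list.

    Member positions add |score|^exponent normalized by the member total;
    non-members subtract 1/(N − n_set).  Returned curve has length N; the
    enrichment score is its maximum-magnitude value.
    """
    n = len(is_member)
    n_set = int(is_member.sum())
    if n_set == 0 or n_set == n:
        raise InputError("gene set must be a proper non-empty subset of the ranking")
    w = np.abs(scores) ** weight_exponent
    w_hit = np.where(is_member, w, 0.0)
    total = w_hit.sum()
    if total == 0:  # all member scores zero: fall back to unweighted steps
        w_hit = is_member.astype(float)
        total = w_hit.sum()
    steps = w_hit / total - (~is_member) / (n - n_set)
    return np.cumsum(steps)


def preranked_enrichment(ranked: pd.DataFrame, gene_set, weight_exponent: float = 1.0,
                         n_perm: int = 1000, seed: int = 0) -> EnrichmentScoreResult:
    """Preranked enrichment score of a gene set with a permutation null.

    ``ranked`` is the output of :func:`rank_by_correlation` (or any frame
    with ``gene`` and ``r`` columns in rank order).  ES is the signed
    maximum-magnitude deviation of the running sum.  The null distribution
    comes from ``n_perm`` random gene sets of the same effective size drawn
    from the ranking; nominal_p = (1 + #{|ES_perm| >= |ES|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100")
    genes = ranked["gene"].to_numpy()
    scores = ranked["r"].to_numpy(float)
    member = np.isin(genes, list(gene_set))
    n_set = int(member.sum())
    if n_set == 0 or n_set == len(genes):
        return EnrichmentScoreResult(np.nan, np.nan, n_perm, seed, n_set, untestable=True)

    curve = running_enrichment_curve(member, scores, weight_exponent)
    es = float(curve[np.argmax(np.abs(curve))])

    rng = np.random.default_rng(seed)
    n = len(genes)
    exceed = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=n_set, replace=False)
        m = np.zeros(n, dtype=bool)
        m[idx] = True
        c = running_enrichment_curve(m, scores, weight_exponent)
        if np.max(np.abs(c)) >= abs(es):
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return EnrichmentScoreResult(es, float(p), n_perm, seed, n_set)
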