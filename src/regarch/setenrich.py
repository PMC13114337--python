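"""Gene-set overlap with significant compartment loci and DE intersection.

Three pieces: mapping genes to the 100-kb bins their bodies overlap;
Fisher-exact enrichment of gene sets in significant bins (SigBins) or merged
blocks (SigBlocks); a Fisher test contrasting the A/B compartment
composition of two cohorts' top-ranked coexpression neighborhoods; and the
four-quadrant intersection of two differential-expression tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .utils import InputError, bh_adjust, odds_ratio_haldane

__all__ = [
    "map_genes_to_bins",
    "fisher_enrichment",
    "enrichment_by_level",
    "gene_compartment_labels",
    "neighborhood_composition_test",
    "DEQuadrants",
    "intersect_de",
]


def map_genes_to_bins(gene_intervals: pd.DataFrame, bins: pd.DataFrame) -> dict:
    """Map each gene to the set of retained bins its interval intersects.

    Intervals are BED-style half-open; genes overlapping no retained bin are
    omitted (they fall outside the enrichment universe).
    """
    for col in ("chrom", "start", "end"):
        if col not in gene_intervals.columns:
            raise InputError(f"gene intervals lack column {col!r}")
    if (gene_intervals["end"] <= gene_intervals["start"]).any():
        raise InputError("malformed gene interval: end <= start")
    out: dict = {}
    for chrom, gsub in gene_intervals.groupby("chrom", sort=False):
        b = bins[bins["chrom"] == chrom].sort_values("start")
        if b.empty:
            continue
        bs, be = b["start"].to_numpy(), b["end"].to_numpy()
        ids = b.index.to_numpy()
        # half-open overlap: gene.start < bin.end and gene.end > bin.start
        lo = np.searchsorted(be, gsub["start"].to_numpy(), side="right")
        hi = np.searchsorted(bs, gsub["end"].to_numpy(), side="left")
        for gene, l, h in zip(gsub.index, lo, hi):
            hit = set(ids[l:h])
            if hit:
                out[gene] = out.get(gene, set()) | hit
    return out


def fisher_enrichment(gene_sets: dict, significant_bins: set, gene_bin_map: dict,
                      level: str = "SigBins") -> pd.DataFrame:
    """Fisher-exact enrichment of gene sets among genes hitting significant loci.

    The universe is every mapped gene; a gene "overlaps" iff at least one of
    its bins belongs to ``significant_bins``.  Odds ratios use the
    cross-product with Haldane 0.5 correction on zero cells; q-values are BH
    across the supplied set collection.  Sets empty after intersection with
    the universe are flagged untestable (missing OR/p).
    """
    universe = set(gene_bin_map)
    if not universe:
        raise InputError("empty gene-bin map")
    overlapping = {g for g, bs in gene_bin_map.items() if bs & significant_bins}
    rows = []
    for name, genes in gene_sets.items():
        genes = set(genes)
        discarded = len(genes - universe)
        genes &= universe
        if not genes:
            rows.append({"set_name": name, "level": level, "untestable": True,
                         "n_set": 0, "n_discarded": discarded,
                         "a": 0, "b": 0, "c": 0, "d": 0,
                         "odds_ratio": np.nan, "p_value": np.nan})
            continue
        a = len(genes & overlapping)
        b = len(genes) - a
        c = len(overlapping) - a
        d = len(universe) - a - b - c
        table = [[a, b], [c, d]]
        p = stats.fisher_exact(table, alternative="two-sided")[1]
        rows.append({"set_name": name, "level": level, "untestable": False,
                     "n_set": len(genes), "n_discarded": discarded,
                     "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds_ratio_haldane(table), "p_value": p})
    res = pd.DataFrame(rows)
    res["q_value"] = bh_adjust(res["p_value"])
    return res


def enrichment_by_level(gene_sets: dict, results: pd.DataFrame, blocks: pd.DataFrame,
                        gene_bin_map: dict, q_threshold: float = 0.05) -> pd.DataFrame:
    """Run enrichment at both locus levels: individual significant bins
    (SigBins) and bins inside merged blocks (SigBlocks)."""
    sig_bins = set(results.index[results["q_value"] < q_threshold])
    block_bins: set = set()
    for members in blocks.get("member_bin_ids", pd.Series(dtype=object)):
        block_bins |= set(members)
    parts = [fisher_enrichment(gene_sets, sig_bins, gene_bin_map, level="SigBins"),
             fisher_enrichment(gene_sets, block_bins, gene_bin_map, level="SigBlocks")]
    return pd.concat(parts, ignore_index=True)


def gene_compartment_labels(call_matrix: pd.DataFrame, gene_bin_map: dict) -> pd.Series:
    """Majority A/B label per gene from cohort-consensus bin calls.

    A bin is consensus-A when more than half of its non-missing sample calls
    are A.  A gene takes the majority label of its bins; ties at either level
    leave the gene unlabeled (excluded).
    """
    frac_a = (call_matrix == "A").sum(axis=1) / call_matrix.notna().sum(axis=1)
    bin_label = pd.Series(np.where(frac_a > 0.5, "A", np.where(frac_a < 0.5, "B", None)),
                          index=call_matrix.index, dtype=object)
    labels = {}
    for gene, bs in gene_bin_map.items():
        ls = bin_label.reindex(sorted(bs)).dropna()
        n_a, n_b = int((ls == "A").sum()), int((ls == "B").sum())
        if n_a > n_b:
            labels[gene] = "A"
        elif n_b > n_a:
            labels[gene] = "B"
    return pd.Series(labels, dtype=object, name="compartment")


def neighborhood_composition_test(ranked_a, ranked_b, labels_a: pd.Series,
                                  labels_b: pd.Series, k: int = 500) -> dict:
    """Fisher test of A/B composition between two cohorts' top-K neighborhoods.

    ``ranked_a``/``ranked_b`` are gene lists in rank order (best first);
    labels map gene -> "A"/"B" per cohort.  Unlabeled genes inside the top K
    are excluded from the counts.
    """
    def counts(ranked, labels):
        genes = list(ranked)
        if k > len(genes):
            warnings.warn(f"K={k} exceeds ranked list length {len(genes)}; truncating")
        top = genes[:k]
        ls = labels.reindex(top).dropna()
        return int((ls == "A").sum()), int((ls == "B").sum())

    a1, b1 = counts(ranked_a, labels_a)
    a2, b2 = counts(ranked_b, labels_b)
    table = [[a1, b1], [a2, b2]]
    p = stats.fisher_exact(table, alternative="two-sided")[1]
    return {"table": table, "odds_ratio": odds_ratio_haldane(table), "p_value": p}


@dataclass
class DEQuadrants:
    """Concordant/discordant intersection of two DE tables."""

    up_both: set
    down_both: set
    upA_downB: set
    downA_upB: set


def _de_calls(table: pd.DataFrame, lfc_threshold: float, q_threshold: float) -> pd.Series:
    for col in ("gene", "log2fc", "padj"):
        if col not in table.columns:
            raise InputError(f"DE table lacks column {col!r}")
    t = table.copy()
    if t["gene"].duplicated().any():
        warnings.warn("duplicate gene symbols in DE table; keeping smallest padj")
        t = t.sort_values("padj", kind="mergesort").drop_duplicates("gene", keep="first")
    sig = t["padj"] < q_threshold
    call = pd.Series("ns", index=t["gene"].to_numpy(), dtype=object)
    call[np.asarray(sig & (t["log2fc"] > lfc_threshold))] = "up"
    call[np.asarray(sig & (t["log2fc"] < -lfc_threshold))] = "down"
    return call


def intersect_de(table_a: pd.DataFrame, table_b: pd.DataFrame,
                 lfc_threshold: float = 0.6, q_threshold: float = 0.05) -> DEQuadrants:
    """Cross two DE tables into concordant/discordant quadrants.

    A gene is up (down) in a table when log2FC > threshold (< −threshold)
    with adjusted p below ``q_threshold``; genes not significant in both
    tables fall in no quadrant.
    """
    ca, cb = _de_calls(table_a, lfc_threshold, q_threshold), \
        _de_calls(table_b, lfc_threshold, q_threshold)
    common = ca.index.intersection(cb.index)
    quads = {("up", "up"): set(), ("down", "down"): set(),
             ("up", "down"): set(), ("down", "up"): set()}
    for g in common:
        key = (ca[g], cb[g])
        if key in quads:
            quads[key].add(g)
    return DEQuadrants(up_both=quads[("up", "up")], down_both=quads[("down", "down")],
                       upA_downB=quads[("up", "down")], downA_upB=quads[("down", "up")])
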