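"""Methylation-derived A/B chromatin compartments and stratified comparison.

Pipeline: aggregate probe betas into non-overlapping 100-kb bins; derive
robust per-sample scores oriented against an external compartment
eigenvector reference so that positive means A/open; call A/B per
(bin, sample); compare the open fraction between two strata per bin
(Δp_open = p_open_high − p_open_low) with Fisher's exact test and BH
correction across bins; merge runs of ≥3 consecutive significant bins into
blocks; summarize direction and effect size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .utils import InputError, ConfigError, bh_adjust

__all__ = [
    "CompartmentCallSet",
    "aggregate_probes_to_bins",
    "orient_and_call",
    "stratified_open_fraction",
    "test_bins",
    "merge_significant_blocks",
    "summarize_compartment_shift",
    "tile_bins",
]


@dataclass
class CompartmentCallSet:
    """Oriented per-(bin, sample) compartment scores and A/B calls.

    ``score`` is positive for A/open-like bins; ``call`` holds "A", "B" or
    NaN (missing).  A call is "A" iff the oriented score is > 0; a score of
    exactly 0 yields a missing call.
    """

    score: pd.DataFrame
    call: pd.DataFrame
    retained_bins: list
    bins: pd.DataFrame  # bin_id index: chrom, start, end


def tile_bins(chrom_lengths: dict, width: int = 100_000) -> pd.DataFrame:
    """Tile each chromosome into non-overlapping fixed-width bins.

    The terminal bin of a chromosome may be shorter than ``width``.
    """
    recs = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, width)
        for s in starts:
            recs.append((chrom, int(s), int(min(s + width, length))))
    df = pd.DataFrame(recs, columns=["chrom", "start", "end"])
    df.index.name = "bin_id"
    return df


def aggregate_probes_to_bins(beta: pd.DataFrame, probes: pd.DataFrame,
                             bins: pd.DataFrame, min_probes: int = 3) -> pd.DataFrame:
    """Mean beta per (bin, sample).

    Probes are assigned to the unique bin containing their start coordinate
    (bins are non-overlapping, half-open).  Bins with fewer than
    ``min_probes`` assigned probes are dropped; per cell, missing probe
    values are ignored and the cell is missing only if all its probes are.
    """
    if beta.empty:
        raise InputError("empty beta matrix")
    if min_probes < 1:
        raise ConfigError("min_probes must be >= 1")
    common = beta.index.intersection(probes.index)
    if len(common) < len(beta):
        warnings.warn(f"{len(beta) - len(common)} probes lack positions; skipped")
    assign = pd.Series(pd.NA, index=common, dtype="object")
    for chrom, sub in probes.loc[common].groupby("chrom", sort=False):
        b = bins[bins["chrom"] == chrom].sort_values("start")
        if b.empty:
            continue
        idx = np.searchsorted(b["start"].to_numpy(), sub["start"].to_numpy(), side="right") - 1
        ok = (idx >= 0) & (sub["start"].to_numpy() < b["end"].to_numpy()[np.clip(idx, 0, None)])
        assign.loc[sub.index[ok]] = b.index.to_numpy()[idx[ok]]
    n_out = int(assign.isna().sum())
    if n_out:
        warnings.warn(f"{n_out} probes fall outside all bins; skipped")
    assign = assign.dropna()
    if assign.empty:
        raise InputError("no probe overlaps any bin")
    grouped = beta.loc[assign.index].groupby(assign.astype(int))
    counts = grouped.size()
    keep = counts[counts >= min_probes].index
    out = grouped.mean()  # NaN-aware: all-NaN cells stay NaN
    out = out.loc[keep].sort_index()
    out.index.name = "bin_id"
    return out


def orient_and_call(bin_matrix: pd.DataFrame, reference: pd.DataFrame) -> CompartmentCallSet:
    """Robust per-sample scores, globally oriented by the reference track.

    Per sample, score = −(beta − median) / MAD over retained bins, so lower
    methylation maps to higher (more open) score.  Per chromosome, if the
    Pearson correlation between the cohort-mean score and the reference
    eigenvector is negative, all scores on that chromosome are negated; the
    pipeline is thereby agnostic to the true methylation–openness direction.
    Samples with MAD = 0 get all-missing calls.
    """
    if bin_matrix.shape[1] < 2:
        raise InputError("need at least 2 samples")
    covered = bin_matrix.index.intersection(reference.index)
    if len(covered) == 0:
        raise InputError("reference track overlaps no retained bin")
    x = bin_matrix.loc[covered]
    med = x.median(axis=0, skipna=True)
    mad = (x - med).abs().median(axis=0, skipna=True)
    degenerate = mad == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} sample(s) with zero MAD; calls set missing")
    score = -(x - med) / mad.replace(0, np.nan)

    ref = reference.loc[covered]
    for chrom, sub in ref.groupby("chrom", sort=False):
        mean_score = score.loc[sub.index].mean(axis=1, skipna=True)
        valid = mean_score.notna() & sub["value"].notna()
        if valid.sum() >= 2 and np.nanstd(mean_score[valid]) > 0:
            r = np.corrcoef(mean_score[valid], sub.loc[valid, "value"])[0, 1]
            if r < 0:
                score.loc[sub.index] = -score.loc[sub.index]

    call = pd.DataFrame(np.where(score > 0, "A", np.where(score < 0, "B", None)),
                        index=score.index, columns=score.columns)
    call = call.where(score.notna() & (score != 0))
    bins_meta = ref[["chrom"]].copy()
    for col in ("start", "end"):
        if col in reference.columns:
            bins_meta[col] = ref[col]
    return CompartmentCallSet(score=score, call=call,
                              retained_bins=list(covered), bins=bins_meta)


def _check_strata(columns, strata: pd.Series) -> pd.Series:
    s = strata.reindex(columns)
    bad = set(s.dropna().unique()) - {"high", "low"}
    if bad:
        raise InputError(f"unknown stratum labels: {sorted(bad)}")
    return s


def _open_counts(calls: CompartmentCallSet, strata: pd.Series):
    s = _check_strata(calls.call.columns, strata)
    out = {}
    for grp in ("high", "low"):
        cols = s.index[s == grp]
        sub = calls.call[cols]
        out[grp] = ((sub == "A").sum(axis=1), sub.notna().sum(axis=1))
    return out


def stratified_open_fraction(calls: CompartmentCallSet, strata: pd.Series) -> pd.DataFrame:
    """Per-bin fraction of samples called A/open in each stratum and Δp_open.

    Fractions are over non-missing calls; the closed fraction is the
    complement.  A bin with no non-missing call in a stratum gets missing
    fractions.
    """
    counts = _open_counts(calls, strata)
    a_h, n_h = counts["high"]
    a_l, n_l = counts["low"]
    p_h = a_h / n_h.replace(0, np.nan)
    p_l = a_l / n_l.replace(0, np.nan)
    return pd.DataFrame({"p_open_high": p_h, "p_open_low": p_l,
                         "delta_p_open": p_h - p_l,
                         "n_high": n_h, "n_low": n_l})


def test_bins(calls: CompartmentCallSet, strata: pd.Series,
              method: str = "fisher") -> pd.DataFrame:
    """Per-bin two-sample test of the A/B call distribution between strata.

    ``fisher``: two-sided Fisher exact test on the 2x2 table
    (A/B x high/low).  ``ztest``: pooled two-proportion z test.  Bins with an
    empty stratum are excluded from testing and from the BH family.
    """
    if method not in {"fisher", "ztest"}:
        raise ConfigError(f"unsupported method: {method}")
    counts = _open_counts(calls, strata)
    a_h, n_h = counts["high"]
    a_l, n_l = counts["low"]
    frac = stratified_open_fraction(calls, strata)
    testable = (n_h > 0) & (n_l > 0)

    p = np.full(len(frac), np.nan)
    ah, nh = a_h.to_numpy(float), n_h.to_numpy(float)
    al, nl = a_l.to_numpy(float), n_l.to_numpy(float)
    if method == "fisher":
        for i in np.flatnonzero(testable.to_numpy()):
            table = [[ah[i], nh[i] - ah[i]], [al[i], nl[i] - al[i]]]
            p[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            pool = (ah + al) / (nh + nl)
            se = np.sqrt(pool * (1 - pool) * (1 / nh + 1 / nl))
            z = (ah / nh - al / nl) / se
        mask = testable.to_numpy()
        p[mask] = np.where(np.isfinite(z[mask]), 2 * stats.norm.sf(np.abs(z[mask])), 1.0)

    res = frac.copy()
    res["p_value"] = p
    res["q_value"] = bh_adjust(p)
    res = res[testable]
    res = res.join(calls.bins, how="left")
    return res.sort_values(["chrom", "start"]) if "start" in res.columns else res


def merge_significant_blocks(results: pd.DataFrame, q_threshold: float = 0.05,
                             min_run: int = 3, bin_width: int = 100_000) -> pd.DataFrame:
    """Merge maximal runs of consecutive significant bins into blocks.

    Bins are consecutive when they are genomically adjacent on the same
    chromosome (end of one equals start of the next); an untested or dropped
    bin therefore breaks a run.  Runs shorter than ``min_run`` are discarded.
    """
    req = {"chrom", "start", "end", "q_value"}
    if not req.issubset(results.columns):
        raise InputError(f"results must carry columns {sorted(req)}")
    df = results.sort_values(["chrom", "start"])
    blocks = []
    run: list = []

    def flush():
        if len(run) >= min_run:
            rows = df.loc[run]
            blocks.append({"chrom": rows["chrom"].iloc[0],
                           "start": int(rows["start"].iloc[0]),
                           "end": int(rows["end"].iloc[-1]),
                           "n_bins": len(run),
                           "member_bin_ids": list(run)})
        run.clear()

    prev_chrom, prev_end = None, None
    for bin_id, row in df.iterrows():
        sig = bool(row["q_value"] < q_threshold) if pd.notna(row["q_value"]) else False
        contiguous = row["chrom"] == prev_chrom and row["start"] == prev_end
        if sig:
            if run and not contiguous:
                flush()
            run.append(bin_id)
        else:
            flush()
        prev_chrom, prev_end = row["chrom"], row["end"]
    flush()
    return pd.DataFrame(blocks, columns=["chrom", "start", "end", "n_bins", "member_bin_ids"])


def summarize_compartment_shift(results: pd.DataFrame, blocks: pd.DataFrame,
                                q_threshold: float = 0.05) -> dict:
    """Cohort-level summary of the stratified compartment comparison.

    Reports the number of tested and significant bins, how many significant
    bins shift toward A/open in the high stratum (Δp_open > 0) and the
    corresponding percentage, the median and IQR of Δp_open among significant
    bins, and block count / length statistics in bp.
    """
    if results.empty:
        raise InputError("empty results")
    sig = results[results["q_value"] < q_threshold]
    n_sig = len(sig)
    out = {
        "n_tested": int(len(results)),
        "n_significant": int(n_sig),
        "n_direction_positive": int((sig["delta_p_open"] > 0).sum()),
        "n_blocks": int(len(blocks)),
    }
    if n_sig:
        out["percent_direction_positive"] = 100.0 * out["n_direction_positive"] / n_sig
        d = sig["delta_p_open"]
        out["median_delta_p_open"] = float(d.median())
        out["delta_p_open_q25"] = float(d.quantile(0.25))
        out["delta_p_open_q75"] = float(d.quantile(0.75))
    else:
        out["percent_direction_positive"] = np.nan
        out["median_delta_p_open"] = np.nan
        out["delta_p_open_q25"] = np.nan
        out["delta_p_open_q75"] = np.nan
    if len(blocks):
        lengths = (blocks["end"] - blocks["start"]).astype(float)
        out["median_block_bp"] = float(lengths.median())
        out["max_block_bp"] = float(lengths.max())
    else:
        out["median_block_bp"] = np.nan
        out["max_block_bp"] = np.nan
    return out
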