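"""Optimal survival cutpoint by log-rank scan and cohort dichotomization.

Candidate thresholds are the distinct marker values whose induced split
keeps both groups inside a quantile window (default 10–90%); the selected
cutpoint maximizes the absolute standardized log-rank statistic

    z = (O − E) / sqrt(V),

where O − E and the hypergeometric variance V accumulate over distinct
event times with the simultaneous-risk-set convention for ties.
Significance of max |z| is assessed by permuting marker values against the
(time, event) pairs, which accounts for the selection over candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .utils import InputError

__all__ = ["logrank_statistic", "scan_cutpoint", "dichotomize", "CutpointResult"]


def _logrank_groups(times: np.ndarray, events: np.ndarray, groups: np.ndarray):
    """Vectorized log-rank accumulation for K candidate group indicators.

    ``groups`` is a (K, n) boolean matrix; returns (O-E, V, z) arrays of
    length K, each computed for the True group.
    """
    order = np.argsort(times, kind="mergesort")
    ts = times[order]
    es = events[order].astype(bool)
    g = groups[:, order].astype(float)
    n = len(ts)

    ev_times = np.unique(ts[es])
    if len(ev_times) == 0:
        raise InputError("no events: log-rank statistic undefined")
    first = np.searchsorted(ts, ev_times, side="left")
    last = np.searchsorted(ts, ev_times, side="right")
    n_risk = (n - first).astype(float)
    event_ts = ts[es]
    d = (np.searchsorted(event_ts, ev_times, side="right")
         - np.searchsorted(event_ts, ev_times, side="left")).astype(float)

    # at-risk group counts: suffix sums evaluated at each event time
    suffix = np.cumsum(g[:, ::-1], axis=1)[:, ::-1]
    n1 = suffix[:, first]
    # events in group at each event time
    ge = g * es
    cum = np.concatenate([np.zeros((g.shape[0], 1)), np.cumsum(ge, axis=1)], axis=1)
    d1 = cum[:, last] - cum[:, first]

    frac = n1 / n_risk
    oe = (d1 - d * frac).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vj = d * frac * (1 - frac) * np.where(n_risk > 1, (n_risk - d) / (n_risk - 1), 0.0)
    var = vj.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, oe / np.sqrt(var), 0.0)
    return oe, var, z


def logrank_statistic(times, events, groups):
    """Two-group log-rank statistic (O − E, variance, z) for one split.

    ``groups`` holds exactly two labels; the statistic is accumulated for
    the lexicographically larger label (so swapping labels negates z).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise InputError("exactly two groups required")
    mask = (groups == labels[-1])[None, :]
    oe, var, z = _logrank_groups(times, events, mask)
    return float(oe[0]), float(var[0]), float(z[0])


@dataclass
class CutpointResult:
    cutpoint: float
    max_abs_z: float
    perm_p: float
    n_high: int
    n_low: int
    scan_window: tuple
    n_candidates: int
    n_perm: int
    seed: int


def _candidate_thresholds(marker: np.ndarray, q_low: float, q_high: float) -> np.ndarray:
    """Distinct marker values whose split (> v vs <= v) keeps the low-group
    fraction inside [q_low, q_high]."""
    n = len(marker)
    vals, counts = np.unique(marker, return_counts=True)
    frac_low = np.cumsum(counts) / n
    ok = (frac_low >= q_low) & (frac_low <= q_high) & (frac_low < 1.0)
    return vals[ok]


def scan_cutpoint(marker, times, events, q_low: float = 0.1, q_high: float = 0.9,
                  n_perm: int = 1000, seed: int = 0) -> CutpointResult:
    """Scan admissible thresholds for the maximal |log-rank z| split.

    The permutation p-value reshuffles marker values against the fixed
    (time, event) pairs and recomputes the scan maximum, so the returned
    ``perm_p`` is adjusted for the threshold selection.  Ties in |z| resolve
    to the smallest candidate value, independent of input order.
    """
    marker = np.asarray(marker, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    n = len(marker)
    if n < 20:
        raise InputError("need at least 20 subjects")
    if events.sum() < 5:
        raise InputError("need at least 5 events")
    cands = _candidate_thresholds(marker, q_low, q_high)
    if len(cands) == 0:
        raise InputError("no admissible candidate threshold in the scan window")

    def scan_max(mk: np.ndarray):
        groups = mk[None, :] > cands[:, None]  # True = high group
        _, _, z = _logrank_groups(times, events, groups)
        absz = np.abs(z)
        best = int(np.argmax(absz))  # first (= smallest candidate) on ties
        return float(cands[best]), float(absz[best])

    cut, max_abs_z = scan_max(marker)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        _, zstar = scan_max(rng.permutation(marker))
        if zstar >= max_abs_z:
            exceed += 1
    perm_p = (1 + exceed) / (n_perm + 1)
    n_high = int((marker > cut).sum())
    return CutpointResult(cutpoint=cut, max_abs_z=max_abs_z, perm_p=perm_p,
                          n_high=n_high, n_low=n - n_high,
                          scan_window=(q_low, q_high), n_candidates=len(cands),
                          n_perm=n_perm, seed=seed)


def dichotomize(marker: pd.Series, cutpoint: float) -> pd.Series:
    """Label samples "high" (marker > cutpoint) or "low" (ties go low)."""
    m = pd.Series(marker)
    if not (m.min() <= cutpoint <= m.max()):
        raise InputError("cutpoint outside the observed marker range")
    labels = pd.Series(np.where(m > cutpoint, "high", "low"), index=m.index,
                       name="stratum", dtype=object)
    if labels.nunique() < 2:
        raise InputError("cutpoint leaves one stratum empty")
    return labels
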