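"""Shared statistical utilities and seeded random-stream plumbing."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "odds_ratio_haldane", "stream_rng", "InputError", "ConfigError"]


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class ConfigError(ValueError):
    """Configuration value outside its documented range."""


#: Fixed stream identifiers: every module draws randomness from
#: ``default_rng([STREAMS[name], root_seed])`` so that datasets are
#: reproducible individually and jointly from one root seed.
STREAMS = {
    "compartments": 101,
    "expression": 202,
    "survival": 303,
    "pockets": 404,
    "cutpoint_perm": 505,
    "enrichment_perm": 606,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Return the named child generator of a root seed.

    Parameters
    ----------
    seed : root seed for the whole analysis.
    stream : one of the keys of :data:`STREAMS`.
    """
    return np.random.default_rng([STREAMS[stream], int(seed)])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    Missing values (NaN) are passed through unchanged and excluded from the
    family; input order is preserved.  q_i = min_{j>=rank(i)} p_(j) * m / j,
    clipped to 1, so q >= p elementwise.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return out
    pm = p[mask]
    if (pm < 0).any() or (pm > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    out[mask] = multipletests(pm, method="fdr_bh")[1]
    return out


def odds_ratio_haldane(table) -> float:
    """Cross-product odds ratio of a 2x2 table with Haldane–Anscombe 0.5
    continuity correction applied when any cell is zero."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise InputError("expected a non-negative 2x2 table")
    if (t == 0).any():
        t = t + 0.5
    return float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
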