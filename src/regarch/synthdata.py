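"""Seeded synthetic datasets with ground truth for every pipeline stage.

The generators emulate the statistical structure each analysis stage assumes:

* a probe-level methylation beta matrix over one pseudo-chromosome tiled in
  100-kb bins, with latent per-(bin, sample) open/closed chromatin states
  whose open fraction differs between two strata by a controlled ``delta_open``
  in a chosen subset of bins;
* a gene expression matrix with an anchor gene, cofactor genes whose Pearson
  correlation with the anchor is stratum-specific, target genes mildly
  coupled to the anchor, and uncorrelated background genes;
* right-censored exponential survival times whose hazard changes at a known
  marker threshold;
* per-tool binding-pocket tables with boundary jitter, plus a per-residue
  confidence track and mutation counts.

Every dataset carries a :class:`SyntheticTruth` describing the generating
parameters so that recovery can be tested.  All randomness flows from one
root seed through the named streams in :mod:`regarch.utils`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .utils import ConfigError, stream_rng

BIN_WIDTH = 100_000
CHROM = "chr1"

#: methylation mixture means: open/A-like bins are hypomethylated.
OPEN_BETA_MEAN = 0.3
CLOSED_BETA_MEAN = 0.7

_DEFAULT_COFACTORS = (
    ("COF01", 0.60, 0.15),
    ("COF02", 0.55, 0.10),
    ("COF03", 0.60, 0.20),
    ("COF04", 0.50, 0.05),
    ("COF05", 0.40, 0.40),
    ("COF06", 0.25, 0.25),
    ("COF07", 0.00, 0.00),
    ("COF08", 0.50, 0.50),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the reference simulation used throughout the test
    suite: two strata of 60 samples, 200 bins of 5 probes, 20% of bins
    shifted by ``delta_open`` = 0.3, an eight-gene cofactor panel with four
    rewired members (Δr ≈ 0.45), a threshold survival effect with hazard
    ratio 3, and four pocket-detection pseudo-tools.
    """

    seed: int = 0
    n_samples_per_stratum: int = 60
    n_bins: int = 200
    probes_per_bin: int = 5
    delta_open: float = 0.3
    frac_shifted_bins: float = 0.2
    beta_noise_sd: float = 0.1
    n_genes: int = 1000
    cofactor_spec: Sequence[tuple[str, float, float]] = _DEFAULT_COFACTORS
    n_target_genes: int = 50
    target_r: float = 0.35
    survival_cutpoint: float = 0.0
    hazard_ratio_true: float = 3.0
    censor_rate: float = 0.3
    n_tools: int = 4
    pocket_jitter: int = 2
    protein_length: int = 452
    n_true_pockets: int = 3
    pocket_size: int = 15
    n_decoys_per_tool: int = 2

    def validate(self) -> None:
        if self.n_samples_per_stratum < 1 or self.n_bins < 1 or self.probes_per_bin < 1:
            raise ConfigError("dimensions must be positive")
        if not 0.0 <= self.delta_open <= 1.0:
            raise ConfigError("delta_open must lie in [0, 1]")
        if not 0.0 <= self.frac_shifted_bins <= 1.0:
            raise ConfigError("frac_shifted_bins must lie in [0, 1]")
        if self.beta_noise_sd <= 0:
            raise ConfigError("beta_noise_sd must be positive")
        for name, r_high, r_low in self.cofactor_spec:
            if abs(r_high) >= 1 or abs(r_low) >= 1:
                raise ConfigError(f"cofactor {name}: |r| must be < 1")
        if self.hazard_ratio_true <= 0:
            raise ConfigError("hazard_ratio_true must be > 0")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError("censor_rate must lie in [0, 1)")
        if self.n_tools < 2:
            raise ConfigError("n_tools must be >= 2")
        if self.pocket_jitter < 0:
            raise ConfigError("pocket_jitter must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters carried beside every dataset."""

    shifted_bin_ids: frozenset = frozenset()
    delta_open: float = float("nan")
    cofactor_r_by_stratum: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    true_cutpoint: float = float("nan")
    true_pocket_residues: tuple = ()


@dataclass
class CompartmentData:
    beta: pd.DataFrame          # probes x samples
    probes: pd.DataFrame        # probe_id index: chrom, start, end
    bins: pd.DataFrame          # bin_id index: chrom, start, end
    reference: pd.DataFrame     # bin_id index: chrom, start, end, value
    strata: pd.Series           # sample -> {"high", "low"}
    latent_open: pd.DataFrame   # bins x samples, bool: generating state
    truth: SyntheticTruth


@dataclass
class ExpressionData:
    expr: pd.DataFrame          # genes x samples
    anchor: str
    strata: pd.Series
    cofactors: list
    target_genes: list
    truth: SyntheticTruth


@dataclass
class SurvivalData:
    marker: pd.Series
    times: pd.Series
    events: pd.Series
    truth: SyntheticTruth


@dataclass
class PocketData:
    tables: dict                # tool -> DataFrame(pocket_id, residue_start, residue_end, metrics...)
    plddt: np.ndarray           # length protein_length, index residue-1
    mutations: np.ndarray       # length protein_length, int counts
    truth: SyntheticTruth


def _sample_names(n_per_stratum: int) -> tuple[list, pd.Series]:
    high = [f"H{i:04d}" for i in range(n_per_stratum)]
    low = [f"L{i:04d}" for i in range(n_per_stratum)]
    strata = pd.Series(["high"] * n_per_stratum + ["low"] * n_per_stratum,
                       index=high + low, name="stratum")
    return high + low, strata


def _truncnorm01(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    a = (0.0 - mean) / sd
    b = (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def gen_compartment_dataset(config: SimConfig) -> CompartmentData:
    """Probe-level beta matrix with latent A/B states and a reference track.

    Each bin carries a base open probability p_b ~ U(0.25, 0.75); in shifted
    bins the high stratum uses min(p_b + delta_open, 0.98).  Open states give
    probe betas from a truncated N(0.3, sd) component, closed states from
    N(0.7, sd).  The reference value is the population mean openness centred
    at 0.5, so its sign matches the generating compartment direction.
    """
    config.validate()
    if config.n_bins < 10:
        raise ConfigError("n_bins must be >= 10")
    rng = stream_rng(config.seed, "compartments")
    nb, ns = config.n_bins, config.n_samples_per_stratum
    samples, strata = _sample_names(ns)

    p_base = rng.uniform(0.25, 0.75, size=nb)
    n_shift = int(round(config.frac_shifted_bins * nb))
    shifted = np.sort(rng.choice(nb, size=n_shift, replace=False))
    p_high = p_base.copy()
    p_high[shifted] = np.minimum(p_base[shifted] + config.delta_open, 0.98)

    # latent open state per (bin, sample)
    u = rng.random((nb, 2 * ns))
    probs = np.concatenate([np.repeat(p_high[:, None], ns, axis=1),
                            np.repeat(p_base[:, None], ns, axis=1)], axis=1)
    latent = u < probs

    # probes evenly spaced inside each bin
    ppb = config.probes_per_bin
    bin_ids = np.repeat(np.arange(nb), ppb)
    offs = ((np.tile(np.arange(ppb), nb) + 0.5) * (BIN_WIDTH / ppb)).astype(int)
    pos = bin_ids * BIN_WIDTH + offs
    probe_ids = [f"cg{i:07d}" for i in range(nb * ppb)]
    probes = pd.DataFrame({"chrom": CHROM, "start": pos, "end": pos + 1},
                          index=pd.Index(probe_ids, name="probe_id"))

    means = np.where(latent[bin_ids, :], OPEN_BETA_MEAN, CLOSED_BETA_MEAN)
    beta = _truncnorm01(rng, means, config.beta_noise_sd)
    beta = pd.DataFrame(beta, index=probes.index, columns=samples)

    starts = np.arange(nb) * BIN_WIDTH
    bins = pd.DataFrame({"chrom": CHROM, "start": starts, "end": starts + BIN_WIDTH},
                        index=pd.RangeIndex(nb, name="bin_id"))
    p_pop = 0.5 * (p_base + p_high)
    reference = bins.assign(value=p_pop - 0.5)

    truth = SyntheticTruth(shifted_bin_ids=frozenset(int(b) for b in shifted),
                           delta_open=config.delta_open)
    latent_df = pd.DataFrame(latent, index=bins.index, columns=samples)
    return CompartmentData(beta, probes, bins, reference, strata, latent_df, truth)


def gen_expression_dataset(config: SimConfig) -> ExpressionData:
    """Expression matrix with stratum-specific anchor–cofactor correlations.

    The anchor is standard normal; each cofactor is r*anchor +
    sqrt(1 - r^2)*noise with the stratum's target r, which makes the target
    the exact population correlation.  Target genes use ``target_r`` in both
    strata; background genes are independent noise.
    """
    config.validate()
    rng = stream_rng(config.seed, "expression")
    ns = config.n_samples_per_stratum
    samples, strata = _sample_names(ns)
    n_total = 2 * ns

    anchor = rng.standard_normal(n_total)
    rows = {"ANCHOR": anchor}
    cof_truth = {}
    for name, r_high, r_low in config.cofactor_spec:
        eps = rng.standard_normal(n_total)
        r = np.where(strata.to_numpy() == "high", r_high, r_low)
        rows[name] = r * anchor + np.sqrt(1 - r ** 2) * eps
        cof_truth[name] = (r_high, r_low)

    targets = [f"TG{i:04d}" for i in range(config.n_target_genes)]
    for g in targets:
        eps = rng.standard_normal(n_total)
        rows[g] = config.target_r * anchor + np.sqrt(1 - config.target_r ** 2) * eps

    n_bg = config.n_genes - len(rows)
    if n_bg < 0:
        raise ConfigError("n_genes too small for anchor + cofactors + targets")
    for i in range(n_bg):
        rows[f"BG{i:04d}"] = rng.standard_normal(n_total)

    expr = pd.DataFrame(rows).T
    expr.columns = samples
    expr.index.name = "gene"
    truth = SyntheticTruth(cofactor_r_by_stratum=cof_truth)
    return ExpressionData(expr, "ANCHOR", strata, [c[0] for c in config.cofactor_spec],
                          targets, truth)


def gen_gene_intervals(config: SimConfig, truth: SyntheticTruth,
                       target_genes: Sequence[str], background_genes: Sequence[str],
                       gene_length: int = 40_000) -> pd.DataFrame:
    """BED-style gene intervals on the pseudo-genome.

    Target genes are placed inside shifted bins (cycled if there are more
    targets than shifted bins); background genes land in uniformly random
    bins.  Used by the enrichment stage, which needs genomic positions for
    the expression dataset's genes.
    """
    rng = stream_rng(config.seed, "expression")
    rng = np.random.default_rng(rng.integers(2 ** 31))  # sub-stream: placement
    shifted = sorted(truth.shifted_bin_ids)
    if not shifted:
        shifted = list(range(config.n_bins))
    recs = []
    for i, g in enumerate(target_genes):
        b = shifted[i % len(shifted)]
        start = b * BIN_WIDTH + int(rng.integers(0, BIN_WIDTH - gene_length)) \
            if BIN_WIDTH > gene_length else b * BIN_WIDTH
        recs.append((g, CHROM, start, start + gene_length))
    for g in background_genes:
        b = int(rng.integers(0, config.n_bins))
        start = b * BIN_WIDTH + int(rng.integers(0, max(1, BIN_WIDTH - gene_length)))
        recs.append((g, CHROM, start, start + gene_length))
    return pd.DataFrame(recs, columns=["gene", "chrom", "start", "end"]).set_index("gene")


def _uniform_censor_bound(lam: np.ndarray, censor_rate: float) -> float:
    """Upper bound c of U(0, c) censoring achieving the requested rate.

    For exponential event rate lam, P(censored) = (1 - exp(-lam*c)) / (lam*c)
    ... averaged over samples; monotone decreasing in c, solved by bisection.
    """
    def prate(c):
        x = lam * c
        return float(np.mean(np.where(x > 1e-12, (1 - np.exp(-x)) / np.maximum(x, 1e-12), 1.0)))

    lo, hi = 1e-9, 1e12
    if prate(hi) > censor_rate:
        return hi
    return float(optimize.brentq(lambda c: prate(c) - censor_rate, lo, hi, xtol=1e-6, rtol=1e-10))


def gen_survival_dataset(config: SimConfig) -> SurvivalData:
    """Marker values plus right-censored exponential survival times.

    Samples with marker below ``survival_cutpoint`` have their baseline
    hazard multiplied by ``hazard_ratio_true`` (low marker = worse outcome).
    Censoring times are uniform on (0, c) with c solved so the expected
    censored fraction equals ``censor_rate``.
    """
    config.validate()
    rng = stream_rng(config.seed, "survival")
    n = 2 * config.n_samples_per_stratum
    names = [f"P{i:04d}" for i in range(n)]
    marker = rng.standard_normal(n)
    lam0 = 1.0 / 365.0
    lam = np.where(marker < config.survival_cutpoint, lam0 * config.hazard_ratio_true, lam0)
    t_event = rng.exponential(1.0 / lam)
    if config.censor_rate == 0:
        times, events = t_event, np.ones(n, dtype=int)
    else:
        c = _uniform_censor_bound(lam, config.censor_rate)
        t_cens = rng.uniform(0, c, size=n)
        times = np.minimum(t_event, t_cens)
        events = (t_event <= t_cens).astype(int)
    idx = pd.Index(names, name="sample")
    truth = SyntheticTruth(true_cutpoint=config.survival_cutpoint)
    return SurvivalData(pd.Series(marker, index=idx, name="marker"),
                        pd.Series(times, index=idx, name="time"),
                        pd.Series(events, index=idx, name="event"), truth)


_TOOL_METRICS = {
    "prank": ("score", "volume"),
    "ftmap": ("hotspot_sum",),
    "mole": ("bottleneck_radius", "length"),
    "dogsite": ("volume", "depth"),
}
_METRIC_BASE = {"score": 5.0, "volume": 600.0, "hotspot_sum": 12000.0,
                "bottleneck_radius": 2.5, "length": 20.0, "depth": 12.0}


def _tool_names(n_tools: int) -> list:
    base = list(_TOOL_METRICS)
    if n_tools <= len(base):
        return base[:n_tools]
    return base + [f"tool{i}" for i in range(len(base), n_tools)]


def gen_pocket_fixture(config: SimConfig) -> PocketData:
    """Per-tool pocket tables, a pLDDT-like confidence track, mutation counts.

    Every true pocket is reported by every tool with up to ``pocket_jitter``
    residues of boundary noise; decoy pockets are private to one tool and sit
    in the low-confidence N-terminal region, disjoint across tools so they can
    never form a cross-tool consensus.  Confidence is >= 85 inside true
    pockets and lower elsewhere.
    """
    config.validate()
    rng = stream_rng(config.seed, "pockets")
    L = config.protein_length
    tools = _tool_names(config.n_tools)
    size = config.pocket_size
    j = config.pocket_jitter

    # true pockets in the high-confidence C-terminal domain, well separated
    domain_start = max(150, L // 3)
    spacing = size + 2 * j + 10
    max_pockets = (L - domain_start - size) // spacing
    if config.n_true_pockets > max_pockets:
        raise ConfigError("too many true pockets for the protein length")
    starts = domain_start + np.arange(config.n_true_pockets) * spacing \
        + rng.integers(0, 5, size=config.n_true_pockets)
    true_pockets = [frozenset(range(int(s), int(s) + size)) for s in starts]

    # per-pocket quality governs the metric magnitudes (pocket 0 strongest)
    quality = np.linspace(1.0, 0.45, config.n_true_pockets)

    tables = {}
    for ti, tool in enumerate(tools):
        metrics = _TOOL_METRICS.get(tool, ("score",))
        recs = []
        for k, pocket in enumerate(true_pockets):
            lo, hi = min(pocket), max(pocket)
            if j > 0:
                lo = int(np.clip(lo + rng.integers(-j, j + 1), 1, L))
                hi = int(np.clip(hi + rng.integers(-j, j + 1), lo, L))
            row = {"pocket_id": f"{tool}_p{k}", "residue_start": lo, "residue_end": hi}
            for m in metrics:
                row[m] = round(_METRIC_BASE[m] * quality[k] * (1 + 0.05 * rng.standard_normal()), 3)
            recs.append(row)
        # decoys: disjoint slots in the N-terminal region, one tool each
        for d in range(config.n_decoys_per_tool):
            slot = ti * config.n_decoys_per_tool + d
            lo = 2 + slot * 16
            hi = lo + 9
            if hi >= domain_start:
                break
            row = {"pocket_id": f"{tool}_decoy{d}", "residue_start": lo, "residue_end": hi}
            for m in metrics:
                row[m] = round(_METRIC_BASE[m] * 0.15 * (1 + 0.1 * rng.standard_normal()), 3)
            recs.append(row)
        tables[tool] = pd.DataFrame(recs)

    plddt = rng.uniform(40, 70, size=L)
    plddt[domain_start - 20:] = rng.uniform(75, 92, size=L - domain_start + 20)
    for pocket in true_pockets:
        lo, hi = min(pocket) - 1, max(pocket)
        plddt[lo:hi] = rng.uniform(85, 98, size=hi - lo)
    plddt = np.round(plddt, 2)
    mutations = rng.poisson(0.05, size=L)

    truth = SyntheticTruth(true_pocket_residues=tuple(true_pockets))
    return PocketData(tables, plddt, mutations, truth)
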