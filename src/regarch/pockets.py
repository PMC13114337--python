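"""Cross-tool consensus of binding-pocket predictions on a protein model.

Per-tool pocket predictions (residue sets plus tool-specific metrics) are
reconciled by residue-level overlap: predictions whose residue sets share a
Jaccard index above a threshold are linked, and connected components
supported by at least ``min_tools`` distinct tools become unified pockets
(UPs).  UPs are prioritized by an equal-weight (configurable) composite of
min–max-normalized per-tool metrics, and annotated with per-residue model
confidence (pLDDT) and mutated-sample counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .utils import InputError

__all__ = ["PocketPrediction", "UnifiedPocket", "parse_pocket_tables",
           "unify_pockets", "prioritize_pockets", "annotate_structure_context",
           "read_plddt_from_pdb", "jaccard"]


@dataclass(frozen=True)
class PocketPrediction:
    tool: str
    pocket_id: str
    residues: frozenset
    metrics: tuple  # sorted (name, value) pairs


@dataclass
class UnifiedPocket:
    up_id: str | None
    residues: frozenset
    supporting_tools: frozenset
    members: tuple
    metrics_by_tool: dict          # "tool:metric" -> best value across members
    composite_score: float = float("nan")
    mean_plddt: float = float("nan")
    min_plddt: float = float("nan")
    high_confidence: bool | None = None
    mutation_count: int | None = None
    flags: list = field(default_factory=list)


def jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def _parse_residue_spec(spec: str) -> set:
    out: set = set()
    for part in str(spec).split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo, hi = part.split("-")
            out |= set(range(int(lo), int(hi) + 1))
        else:
            out.add(int(part))
    return out


def parse_pocket_tables(tables: dict, protein_length: int) -> list:
    """Normalize per-tool pocket tables into :class:`PocketPrediction` records.

    ``tables`` maps tool name -> DataFrame with ``pocket_id`` plus either a
    ``residues`` column ("10-14,20"-style spec) or ``residue_start`` /
    ``residue_end``; any remaining numeric columns become metrics.  Records
    with residues outside [1, protein_length] are rejected with a warning.
    """
    preds = []
    for tool, df in tables.items():
        if df is None or len(df) == 0:
            continue
        res_cols = {"residues"} if "residues" in df.columns else {"residue_start", "residue_end"}
        if not res_cols.issubset(df.columns):
            raise InputError(f"tool {tool!r}: no residue specification columns")
        metric_cols = [c for c in df.columns
                       if c not in res_cols | {"pocket_id", "tool"}
                       and pd.api.types.is_numeric_dtype(df[c])]
        for _, row in df.iterrows():
            if "residues" in res_cols:
                residues = _parse_residue_spec(row["residues"])
            else:
                residues = set(range(int(row["residue_start"]), int(row["residue_end"]) + 1))
            if not residues:
                warnings.warn(f"{tool}:{row['pocket_id']}: empty residue set; rejected")
                continue
            if min(residues) < 1 or max(residues) > protein_length:
                warnings.warn(f"{tool}:{row['pocket_id']}: residue outside "
                              f"[1, {protein_length}]; rejected")
                continue
            metrics = tuple(sorted((c, float(row[c])) for c in metric_cols
                                   if pd.notna(row[c])))
            preds.append(PocketPrediction(tool=str(tool), pocket_id=str(row["pocket_id"]),
                                          residues=frozenset(residues), metrics=metrics))
    return preds


def unify_pockets(predictions, jaccard_min: float = 0.25, min_tools: int = 2) -> list:
    """Connected components of the Jaccard-overlap graph over predictions.

    An edge links two predictions when their residue-set Jaccard index is
    >= ``jaccard_min``; components spanning fewer than ``min_tools`` distinct
    tools are discarded.  Output is independent of input order: members are
    canonically sorted and components ordered by their smallest residue.
    """
    preds = sorted(predictions, key=lambda p: (p.tool, p.pocket_id))
    if not preds:
        raise InputError("no predictions supplied")
    n = len(preds)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for k in range(i + 1, n):
            if jaccard(preds[i].residues, preds[k].residues) >= jaccard_min:
                ri, rk = find(i), find(k)
                if ri != rk:
                    parent[max(ri, rk)] = min(ri, rk)

    comps: dict = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(preds[i])

    ups = []
    for members in comps.values():
        tools = frozenset(p.tool for p in members)
        if len(tools) < min_tools:
            continue
        residues = frozenset().union(*(p.residues for p in members))
        metrics: dict = {}
        for p in members:
            for name, val in p.metrics:
                key = f"{p.tool}:{name}"
                metrics[key] = max(metrics.get(key, -np.inf), val)
        ups.append(UnifiedPocket(up_id=None, residues=residues, supporting_tools=tools,
                                 members=tuple(members), metrics_by_tool=metrics))
    ups.sort(key=lambda u: (min(u.residues), len(u.residues)))
    return ups


def prioritize_pockets(ups, metric_weights: dict | None = None) -> list:
    """Rank UPs by a weighted mean of min–max-normalized metrics.

    Every metric name present in any UP participates; a UP missing a metric
    is assigned that metric's minimum.  Metrics constant across UPs
    contribute 0.5 (uninformative).  Ties resolve by larger residue count,
    then lexicographically by residue content.  UPs are relabeled UP1…UPk in
    descending composite order.
    """
    ups = list(ups)
    if not ups:
        return []
    names = sorted({m for u in ups for m in u.metrics_by_tool})
    if not names:
        raise InputError("no metrics available for prioritization")
    if metric_weights is None:
        metric_weights = {m: 1.0 for m in names}
    if len(ups) == 1:
        u = ups[0]
        u.composite_score = 1.0
        u.flags.append("single_up_degenerate")
        u.up_id = "UP1"
        return ups

    vals = np.full((len(ups), len(names)), np.nan)
    for i, u in enumerate(ups):
        for j, m in enumerate(names):
            if m in u.metrics_by_tool:
                vals[i, j] = u.metrics_by_tool[m]
    col_min = np.nanmin(vals, axis=0)
    vals = np.where(np.isnan(vals), col_min, vals)  # missing -> metric minimum
    col_max = vals.max(axis=0)
    col_min = vals.min(axis=0)
    span = col_max - col_min
    norm = np.where(span > 0, (vals - col_min) / np.where(span > 0, span, 1.0), 0.5)
    w = np.array([metric_weights.get(m, 0.0) for m in names], float)
    if w.sum() <= 0:
        raise InputError("metric weights sum to zero")
    composite = norm @ (w / w.sum())
    for u, c in zip(ups, composite):
        u.composite_score = float(c)
    ups.sort(key=lambda u: (-u.composite_score, -len(u.residues), tuple(sorted(u.residues))))
    for i, u in enumerate(ups, start=1):
        u.up_id = f"UP{i}"
    return ups


def annotate_structure_context(ups, plddt: np.ndarray, mutations: np.ndarray,
                               plddt_min: float = 70.0) -> list:
    """Attach pLDDT and mutation summaries to each UP.

    ``plddt`` and ``mutations`` are per-residue arrays (index = residue − 1).
    A UP is high-confidence when its mean pLDDT >= ``plddt_min``.
    """
    plddt = np.asarray(plddt, float)
    mutations = np.asarray(mutations)
    for u in ups:
        idx = np.array(sorted(u.residues)) - 1
        if idx.min() < 0 or idx.max() >= len(plddt) or idx.max() >= len(mutations):
            raise InputError(f"{u.up_id or 'UP'}: residue beyond confidence/mutation track")
        u.mean_plddt = float(plddt[idx].mean())
        u.min_plddt = float(plddt[idx].min())
        u.high_confidence = bool(u.mean_plddt >= plddt_min)
        u.mutation_count = int(mutations[idx].sum())
    return ups


def read_plddt_from_pdb(path) -> np.ndarray:
    """Per-residue confidence from a PDB file's temperature-factor field.

    AlphaFold models store pLDDT in the B-factor column; values are averaged
    over the atoms of each residue and returned indexed by residue order.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    vals = []
    for model in st:
        for chain in model:
            for residue in chain:
                bs = [atom.b_iso for atom in residue]
                if bs:
                    vals.append(float(np.mean(bs)))
        break  # first model only
    if not vals:
        raise InputError(f"no residues with temperature factors in {path}")
    return np.array(vals)
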