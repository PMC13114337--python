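"""Plain-text readers and writers (TSV matrices, BED-like tables, GMT sets)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .utils import InputError

FLOAT_FMT = "%.6g"


def read_matrix_tsv(path) -> pd.DataFrame:
    """Feature-by-sample matrix: first column is the feature id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise InputError(f"empty matrix: {path}")
    return df


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_bed_like(path, value_name: str | None = None) -> pd.DataFrame:
    """BED-like TSV (0-based half-open): name, chrom, start, end[, value]."""
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "end"}
    if not need.issubset(df.columns):
        raise InputError(f"{path}: expected columns {sorted(need)}")
    df = df.set_index(df.columns[0]) if df.columns[0] not in need else df
    if value_name and value_name not in df.columns:
        raise InputError(f"{path}: expected a {value_name!r} column")
    return df


def write_bed_like(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_strata(path) -> pd.Series:
    """Two-column TSV: sample, stratum (high/low)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected two columns (sample, stratum)")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy(),
                     name="stratum")


def write_strata(strata: pd.Series, path) -> None:
    strata.rename_axis("sample").to_frame().to_csv(path, sep="\t")


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            continue
        sets[parts[0]] = set(g for g in parts[2:] if g)
    if not sets:
        raise InputError(f"no gene sets in {path}")
    return sets


def read_survival(path) -> pd.DataFrame:
    """TSV with columns sample, time, event."""
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "time", "event"}
    if not need.issubset(df.columns):
        raise InputError(f"{path}: expected columns {sorted(need)}")
    return df.set_index("sample")


def read_pocket_tables(paths) -> dict:
    """Per-tool pocket TSVs; each file carries a ``tool`` column."""
    tables = {}
    for p in paths:
        df = pd.read_csv(p, sep="\t")
        if "tool" not in df.columns:
            raise InputError(f"{p}: expected a 'tool' column")
        for tool, sub in df.groupby("tool", sort=False):
            tables[tool] = pd.concat([tables.get(tool, pd.DataFrame()), sub],
                                     ignore_index=True)
    return tables


def read_track_tsv(path, value_col: str, index_col: str = "residue_index"):
    df = pd.read_csv(path, sep="\t")
    if value_col not in df.columns or index_col not in df.columns:
        raise InputError(f"{path}: expected columns {index_col!r}, {value_col!r}")
    return df.set_index(index_col)[value_col]
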