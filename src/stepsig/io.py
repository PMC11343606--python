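"""Readers and writers for the plain-text formats the pipeline uses.

Matrices are TSV/CSV with gene ids in the first column and sample ids in
the header; signatures are one gene per line with ``#`` comments; gene
sets are GMT (name, description, members, tab-separated).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "read_expression_matrix",
    "write_matrix",
    "read_signature",
    "write_signature",
    "read_gmt",
    "write_gmt",
    "read_gene_lengths",
    "read_metadata",
    "read_survival",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(path, counts: bool = False) -> pd.DataFrame:
    """Read a genes x samples matrix; validate ids and cells.

    With ``counts=True`` the values must be non-negative integers and the
    result has integer dtype.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()
        raise InputError(
            f"duplicated gene id(s) in {path.name}: {', '.join(dups[:10])}"
        )
    if df.isna().any().any():
        coords = [
            f"(gene {g}, sample {c})"
            for g in df.index
            for c in df.columns
            if pd.isna(df.at[g, c])
        ]
        raise InputError(f"missing cell(s) in {path.name}: {'; '.join(coords[:10])}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise InputError(f"non-numeric value in {path.name}: {exc}") from exc
    if counts:
        arr = df.to_numpy()
        if (arr < 0).any() or not np.all(arr == np.round(arr)):
            raise InputError(f"{path.name}: counts must be non-negative integers")
        df = df.astype(np.int64)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_signature(path) -> list[str]:
    """One gene id per line; blank lines and ``#`` comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            genes.append(entry)
    if not genes:
        raise InputError(f"signature file {path} contains no genes")
    return genes


def write_signature(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets as ``{name: members}``; descriptions are dropped."""
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InputError(f"{path}:{ln}: GMT line needs name, description, members")
        name, _desc, *members = fields
        if name in sets:
            raise InputError(f"{path}:{ln}: duplicate set name '{name}'")
        sets[name] = [m for m in members if m]
    if not sets:
        raise InputError(f"GMT file {path} contains no sets")
    return sets


def write_gmt(sets: dict, path, description: str = "") -> None:
    lines = [
        "\t".join([name, description, *members]) for name, members in sets.items()
    ]
    Path(path).write_text("".join(f"{line}\n" for line in lines))


def read_gene_lengths(path) -> pd.Series:
    """Two-column TSV: gene id, length in bp."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] != 1:
        raise InputError(f"{path.name}: expected exactly 2 columns")
    s = df.iloc[:, 0].astype(int)
    s.index = s.index.astype(str)
    if (s <= 0).any():
        raise InputError(f"{path.name}: gene lengths must be positive")
    return s


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise InputError(f"{path.name}: duplicated sample id(s)")
    return df


def read_survival(path) -> pd.DataFrame:
    """TSV with columns sample_id, time, event(0/1)."""
    df = read_metadata(path)
    for col in ("time", "event"):
        if col not in df.columns:
            raise InputError(f"survival table missing column '{col}'")
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int).astype(bool)
    return df
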