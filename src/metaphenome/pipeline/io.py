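"""Table I/O helpers: TSV/CSV (empty field = missing) and optional Parquet."""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd


def write_table(table: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix == ".parquet":
        table.to_parquet(path, index=index)
    elif suffix in (".tsv", ".csv"):
        sep = "\t" if suffix == ".tsv" else ","
        table.to_csv(path, sep=sep, index=index, na_rep="")
    else:
        raise ValueError(f"unsupported table extension {suffix!r}")
    return path


def read_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".parquet":
        table = pd.read_parquet(path)
    elif suffix in (".tsv", ".csv"):
        sep = "\t" if suffix == ".tsv" else ","
        try:
            table = pd.read_csv(path, sep=sep, index_col=index_col)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed table {path}: {exc}") from exc
    else:
        raise ValueError(f"unsupported table extension {suffix!r}")
    if index_col is not None and table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"duplicate id {dup!r} in {path}")
    return table


def checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
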