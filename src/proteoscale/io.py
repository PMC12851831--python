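"""Readers and writers for the pipeline's file contracts.

All tabular data travel as tab-delimited text with a header row and the
identifier in the first column.  Gene sets use the GMT convention
(set name, description, then tab-separated members).  Manifests are JSON.
Round-trips are lossless: matrices written with :func:`write_matrix` and read
back with :func:`read_matrix` compare equal, with empty cells mapping to the
missing-value mask (NaN).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_manifest",
    "write_manifest",
]


def read_matrix(path: str | Path, numeric: bool = True) -> pd.DataFrame:
    """Read a TSV matrix (first column = row identifier).

    Empty cells become NaN (the missing mask).  CRLF line endings are
    accepted.  Raises ``ValueError`` naming the offending line on malformed
    numeric input.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if not numeric:
        return df
    try:
        return df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        # locate the first malformed cell for a useful error
        for i, (_, row) in enumerate(df.iterrows(), start=2):
            for val in row:
                if val is not None and not _is_number_or_blank(val):
                    raise ValueError(
                        f"{path}: malformed numeric value {val!r} on line {i}"
                    ) from None
        raise


def _is_number_or_blank(val: object) -> bool:
    if val is None or (isinstance(val, float) and pd.isna(val)):
        return True
    try:
        float(val)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    """Write a matrix as TSV; NaN becomes an empty cell."""
    df.to_csv(Path(path), sep="\t", index_label=index_label, na_rep="")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file: name, description, members...

    Raises ``ValueError`` with the line number on lines with fewer than two
    fields.
    """
    sets: dict[str, set[str]] = {}
    with open(path, newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed GMT line {lineno}")
            name = fields[0]
            sets[name] = {f for f in fields[2:] if f}
    return sets


def write_gmt(sets: Mapping[str, set[str] | list[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read an edge-list TSV (two endpoint columns plus attribute columns)."""
    return pd.read_csv(Path(path), sep="\t", dtype={0: str, 1: str})


def write_edge_list(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), sep="\t", index=False)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_manifest(manifest: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
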