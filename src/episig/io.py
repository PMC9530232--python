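"""Readers and writers for the pipeline's plain-text formats.

Canonical tabular dialect is TSV, UTF-8, '.' decimal separator; gene sets
use the standard GMT layout (one set per line: name, description, members,
tab-separated).  Missing values are written as ``NA`` and accepted
case-insensitively on read.  Every CLI run also writes a JSON manifest
(config echo, seed, package version, input checksums) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .scoring import GeneSet, GeneSetCollection

__all__ = [
    "read_counts",
    "write_counts",
    "read_expression",
    "write_expression",
    "read_table",
    "write_table",
    "read_gmt",
    "write_gmt",
    "write_manifest",
]

_NA_VALUES = ["NA", "na", "Na", "nA", ""]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_NA_VALUES, keep_default_na=False
    )
    return df


def _check_duplicates(index: pd.Index, what: str, path: str | Path) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated(keep=False)]
        locs = {}
        for pos, name in enumerate(index):
            if name in set(dup):
                locs.setdefault(name, []).append(pos + 2)  # 1-based + header line
        msg = "; ".join(f"{k!r} on rows {v}" for k, v in sorted(locs.items()))
        raise ValueError(f"duplicate {what} ids in {path}: {msg}")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read and validate a gene x sample integer count matrix from TSV.

    First column gene id, header sample ids.  Duplicate ids, negative,
    non-numeric or non-integer cells are rejected with their location.
    """
    df = _read_tsv(path)
    _check_duplicates(df.index, "gene", path)
    _check_duplicates(pd.Index(df.columns), "sample", path)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if df[col].isna().any():
            gene = df.index[df[col].isna()][0]
            raise ValueError(f"missing count for gene {gene!r}, sample {col!r} in {path}")
        if bad.any():
            gene = df.index[bad][0]
            raise ValueError(
                f"non-numeric count {df.loc[gene, col]!r} for gene {gene!r}, "
                f"sample {col!r} in {path}"
            )
        df[col] = vals
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative count for gene {df.index[g]!r}, sample {df.columns[s]!r} in {path}"
        )
    frac = arr != np.round(arr)
    if frac.any():
        g, s = np.argwhere(frac)[0]
        raise ValueError(
            f"non-integer count {arr[g, s]} for gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r} in {path}"
        )
    out = df.astype(np.int64)
    out.index.name = "gene"
    return out


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample continuous expression matrix from TSV."""
    df = _read_tsv(path)
    _check_duplicates(df.index, "gene", path)
    _check_duplicates(pd.Index(df.columns), "sample", path)
    out = df.apply(pd.to_numeric, errors="raise")
    out.index.name = "gene"
    return out


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Generic TSV table (metadata, cohort annotations, DE results...)."""
    return pd.read_csv(
        path, sep="\t", index_col=index_col, na_values=_NA_VALUES, keep_default_na=False
    )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT gene-set file (name TAB description TAB members...)."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in set {name!r} removed")
            if not deduped:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name=name, description=desc, genes=tuple(deduped)))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection | Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: dict,
    seed: int | None,
    inputs: Iterable[str | Path] = (),
) -> Path:
    """Write a reproducibility manifest for a CLI run."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "version": __version__,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
    }
    path = out_dir / f"manifest_{command.replace(' ', '_')}.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
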