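"""Readers/writers for the formats the pipeline touches, plus run manifests.

All table output is TSV.  Writers are atomic (temp file in the destination
directory, then rename) so a failing run never leaves partial output.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Mapping

import dendropy
import pandas as pd

__all__ = [
    "read_tree",
    "read_trait_table",
    "read_manifest",
    "read_config",
    "atomic_write_text",
    "atomic_write_df",
    "write_run_manifest",
]


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree; the first tree in the file is used."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True  # seed node is taken as the root
    return tree


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """TSV with a taxon_id column; returned indexed by taxon_id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str})
    if "taxon_id" not in df.columns:
        raise ValueError(f"{path}: trait table must have a taxon_id column")
    return df.set_index("taxon_id")


def read_manifest(path: str | Path) -> list[tuple[str, Path]]:
    """TSV mapping taxon_id -> FASTA path; relative paths resolve against it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"taxon_id", "fasta"} <= set(df.columns):
        raise ValueError(f"{path}: manifest needs columns taxon_id and fasta")
    if df.empty:
        raise ValueError(f"{path}: manifest lists no taxa")
    out = []
    for _, row in df.iterrows():
        fasta = Path(row["fasta"])
        if not fasta.is_absolute():
            fasta = path.parent / fasta
        out.append((str(row["taxon_id"]), fasta))
    return out


def read_config(path: str | Path) -> dict[str, str]:
    """Flat key=value configuration file; '#' lines are comments."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out


def _atomic(path: Path, data: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path: str | Path, text: str) -> Path:
    path = Path(path)
    _atomic(path, text)
    return path


def atomic_write_df(path: str | Path, df: pd.DataFrame, index: bool = False) -> Path:
    path = Path(path)
    _atomic(path, df.to_csv(sep="\t", index=index))
    return path


def write_run_manifest(path: str | Path, params: Mapping) -> Path:
    """Machine-readable record of the parameters that produced an output."""
    from . import __version__

    payload = {"codefidelity_version": __version__, **dict(params)}
    return atomic_write_text(path, json.dumps(payload, indent=2, default=str) + "\n")
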