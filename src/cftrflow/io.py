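"""File formats shared across the pipeline.

Plain-text, versionable formats only: CSV/TSV tables, GMT gene-set
collections, one-identifier-per-line reference lists, STRING-style edge
lists and JSON geometry sidecars. Images travel as TIFF via tifffile.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile
from gseapy import read_gmt  # noqa: F401  (re-exported reader)

LAYOUT_ROLES = {"sample", "NCtrl", "siCFTR", "positive"}


def read_layout(path: str | Path) -> pd.DataFrame:
    """Plate layout CSV with columns well, treatment, role."""
    df = pd.read_csv(path)
    missing = {"well", "treatment", "role"} - set(df.columns)
    if missing:
        raise ValueError(f"layout missing columns: {sorted(missing)}")
    bad = set(df["role"]) - LAYOUT_ROLES
    if bad:
        raise ValueError(f"unknown layout roles: {sorted(bad)}")
    return df


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *map(str, genes)]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(map(str, genes)) + "\n")


def read_category_map(path: str | Path) -> dict[str, str]:
    """TSV of (term, category); a term mapped to two categories is an error."""
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i}: expected 2 tab-separated fields")
        term, cat = parts[0].strip(), parts[1].strip()
        if term in out and out[term] != cat:
            raise ValueError(f"{path}:{i}: term {term!r} mapped to more than one category")
        out[term] = cat
    return out


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Long-format TSV (term id, term name, gene) -> term id -> gene set."""
    df = pd.read_csv(path, sep="\t", names=["term", "name", "gene"], comment="#")
    out: dict[str, set[str]] = {}
    for term, gene in zip(df["term"], df["gene"]):
        out.setdefault(str(term), set()).add(str(gene))
    return out


def write_annotation(annotation: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in annotation.items():
            for g in genes:
                fh.write(f"{term}\t{term}\t{g}\n")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """STRING-export-style TSV: node1, node2, combined_score (0-1 or 0-1000).

    Malformed rows are reported with their line numbers.
    """
    rows, bad = [], []
    lines = Path(path).read_text().splitlines()
    start = 0
    if lines and lines[0].lower().replace(" ", "").startswith("node1"):
        start = 1
    for i, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            bad.append(i)
            continue
        try:
            score = float(parts[2])
        except ValueError:
            bad.append(i)
            continue
        rows.append({"node1": parts[0], "node2": parts[1], "combined_score": score})
    if bad:
        raise ValueError(f"malformed edge rows at lines {bad} of {path}")
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])


def write_geometry(voxel_size_um: tuple[float, float, float], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"voxel_size_um": {"z": voxel_size_um[0], "y": voxel_size_um[1], "x": voxel_size_um[2]}})
    )


def read_geometry(path: str | Path) -> tuple[float, float, float]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"geometry sidecar missing: {path}")
    v = json.loads(path.read_text())["voxel_size_um"]
    return (float(v["z"]), float(v["y"]), float(v["x"]))


def write_tiff(array: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), array)


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))
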