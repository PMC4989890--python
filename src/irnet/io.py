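"""Readers and writers for matrices, edge lists and SIF network exports.

All on-disk formats are delimited text: matrices as TSV with a header row of
column labels and a first column of row labels; edge lists as 3-column TSV
(node_a, node_b, weight); SIF as the whitespace format understood by network
viewers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import FeatureMatrix, LabelledMatrix, TraitMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_edge_list",
    "write_edge_list",
    "write_sif",
]

Edge = tuple[str, str, float]


def read_matrix(path, kind: str = "feature", sep: str = "\t") -> LabelledMatrix:
    """Read a labelled matrix from delimited text.

    ``kind`` selects the returned container: ``"feature"``, ``"trait"`` or
    ``"plain"``.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate column labels in {path}: {dupes[:5]}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"cannot parse matrix file {path}: {exc}") from exc
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ]
    if len(non_numeric):
        for col in non_numeric:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                row = list(df.index).index(bad.index[0]) + 2  # header is row 1
                raise ValueError(
                    f"non-numeric cell in column {col!r} at row {row} of {path}"
                )
        df = df.astype(float)
    cls = {"feature": FeatureMatrix, "trait": TraitMatrix, "plain": LabelledMatrix}[kind]
    return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


def write_matrix(m: LabelledMatrix, path, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    m.to_frame().to_csv(path, sep=sep, float_format="%.12g")


def read_edge_list(path, sep: str = "\t") -> list[Edge]:
    edges: list[Edge] = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and header.split(sep)[-1].strip() not in ("weight", "w"):
            raise ValueError(f"edge list {path} missing header line")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(sep)
            if len(parts) != 3:
                raise ValueError(f"ragged row at line {lineno} of {path}")
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric weight at line {lineno} of {path}"
                ) from exc
            edges.append((parts[0], parts[1], w))
    return edges


def write_edge_list(edges: list[Edge], path, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(sep.join(["node_a", "node_b", "weight"]) + "\n")
        for a, b, w in edges:
            fh.write(sep.join([str(a), str(b), f"{w:.12g}"]) + "\n")


def write_sif(edges: list[Edge], path, relation: str = "aff") -> None:
    """Write edges in SIF format: ``node_a <relation> node_b`` per line."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for a, b, _ in edges:
            fh.write(f"{a} {relation} {b}\n")
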