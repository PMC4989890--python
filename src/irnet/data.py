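"""Core data containers and preprocessing.

The pipeline works on two sample-by-variable matrices measured on the same
samples: a *feature* matrix (e.g. gene-level DNA methylation) and a *trait*
matrix (e.g. mRNA expression).  Both are standardized column-wise before any
regression so that coefficients of different features are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LabelledMatrix",
    "FeatureMatrix",
    "TraitMatrix",
    "ProbeTable",
    "standardize",
    "average_probes_to_genes",
    "intersect_common",
]


def _check_unique(labels, what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return labels


@dataclass
class LabelledMatrix:
    """A dense numeric matrix with unique row (sample) and column labels."""

    values: np.ndarray
    sample_ids: list[str]
    column_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.column_ids = _check_unique(self.column_ids, "column ids")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.column_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.column_ids)} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite (missing?) values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.column_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabelledMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def select_columns(self, ids: list[str]) -> "LabelledMatrix":
        pos = {c: i for i, c in enumerate(self.column_ids)}
        idx = [pos[c] for c in ids]
        return replace(self, values=self.values[:, idx], column_ids=list(ids))


@dataclass
class FeatureMatrix(LabelledMatrix):
    """n_samples x J matrix of regression inputs (methylation-style features)."""

    @property
    def feature_ids(self) -> list[str]:
        return self.column_ids


@dataclass
class TraitMatrix(LabelledMatrix):
    """n_samples x K matrix of regression outputs (expression traits)."""

    @property
    def trait_ids(self) -> list[str]:
        return self.column_ids


@dataclass
class ProbeTable:
    """Probe-level measurements with a probe -> gene mapping.

    Each probe maps to exactly one gene; probes of the same gene are averaged
    into a single gene-level feature column.
    """

    values: np.ndarray
    sample_ids: list[str]
    probe_ids: list[str]
    probe_to_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.probe_ids = _check_unique(self.probe_ids, "probe ids")


def average_probes_to_genes(probes: ProbeTable) -> FeatureMatrix:
    """Collapse probe-level columns to gene-level columns by arithmetic mean.

    Every probe must map to exactly one gene; genes are emitted in
    lexicographic order.
    """
    if not probes.probe_to_gene:
        raise ValueError("no probes mapped")
    missing = [p for p in probes.probe_ids if p not in probes.probe_to_gene]
    if missing:
        raise ValueError(f"probes without gene mapping: {missing[:5]}")
    genes = sorted({probes.probe_to_gene[p] for p in probes.probe_ids})
    cols = np.empty((probes.values.shape[0], len(genes)))
    for gi, gene in enumerate(genes):
        idx = [
            i for i, p in enumerate(probes.probe_ids)
            if probes.probe_to_gene[p] == gene
        ]
        cols[:, gi] = probes.values[:, idx].mean(axis=1)
    return FeatureMatrix(cols, list(probes.sample_ids), genes)


def standardize(m: LabelledMatrix, ddof: int = 1) -> LabelledMatrix:
    """Return a copy with each column scaled to mean 0 and SD 1.

    The SD uses the n-1 (sample) denominator.  Constant columns cannot be
    standardized and raise, naming the offending column.
    """
    mu = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        names = [m.column_ids[i] for i in bad[:5]]
        raise ValueError(f"constant column(s), cannot standardize: {names}")
    return replace(m, values=(m.values - mu) / sd)


def intersect_common(matrices: list[LabelledMatrix]) -> list[LabelledMatrix]:
    """Restrict each matrix to the columns shared by all, in lexicographic order."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices to intersect")
    common = set(matrices[0].column_ids)
    for m in matrices[1:]:
        common &= set(m.column_ids)
    if not common:
        raise ValueError("empty column intersection")
    order = sorted(common)
    return [m.select_columns(order) for m in matrices]
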