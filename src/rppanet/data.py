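"""Core data containers shared across the pipeline stages.

The analysis operates on three kinds of objects: an expression dataset
(samples x antibodies, with a cohort label per sample and per-antibody
annotation), symmetric weighted networks over the antibody set, and a
gold-standard set of unordered antibody pairs used for benchmarking.
Edge identity everywhere is the sorted antibody-id pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GoldStandardNetwork",
    "make_annotation",
    "canonical_pair",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an unordered antibody pair."""
    return (a, b) if a <= b else (b, a)


def make_annotation(
    antibodies: Sequence[str],
    genes: Mapping[str, Sequence[str]],
    phosphospecific: Mapping[str, bool] | None = None,
    phosphosite: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Build a per-antibody annotation table.

    Columns: ``genes`` (tuple of HGNC-style symbols, nonempty),
    ``phosphosite`` (string, possibly empty), ``phosphospecific`` (bool).
    """
    phosphospecific = phosphospecific or {}
    phosphosite = phosphosite or {}
    rows = []
    for ab in antibodies:
        gs = tuple(genes[ab])
        if not gs:
            raise ValueError(f"antibody {ab!r} has an empty gene list")
        rows.append(
            {
                "genes": gs,
                "phosphosite": phosphosite.get(ab, ""),
                "phosphospecific": bool(phosphospecific.get(ab, False)),
            }
        )
    return pd.DataFrame(rows, index=pd.Index(antibodies, name="antibody"))


@dataclass
class ExpressionDataset:
    """Samples x antibodies expression matrix with cohort labels.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Real-valued, rows are samples, columns are antibodies. Must be
        free of missing values (apply a missing-value policy on load).
    cohorts : pandas.Series
        One cohort label per sample, aligned with ``matrix.index``.
    annotation : pandas.DataFrame, optional
        Per-antibody table as built by :func:`make_annotation`.
    """

    matrix: pd.DataFrame
    cohorts: pd.Series
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.matrix.columns.duplicated().any():
            dup = self.matrix.columns[self.matrix.columns.duplicated()][0]
            raise ValueError(f"duplicate antibody id {dup!r}")
        if not self.matrix.index.equals(self.cohorts.index):
            self.cohorts = self.cohorts.reindex(self.matrix.index)
        if self.cohorts.isna().any():
            raise ValueError("every sample needs a cohort label")
        vals = self.matrix.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        if self.annotation is not None:
            missing = set(self.matrix.columns) - set(self.annotation.index)
            if missing:
                raise ValueError(f"antibodies without annotation: {sorted(missing)}")

    @property
    def antibody_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def cohort_names(self) -> list[str]:
        return sorted(self.cohorts.unique())

    def cohort(self, name: str) -> pd.DataFrame:
        """Sub-matrix for one cohort (samples x antibodies)."""
        sel = self.cohorts == name
        if not sel.any():
            raise KeyError(f"unknown cohort {name!r}")
        return self.matrix.loc[sel]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_antibodies(self) -> int:
        return self.matrix.shape[1]


@dataclass
class GoldStandardNetwork:
    """Undirected benchmark edge set over antibodies.

    ``pairs`` holds canonical (sorted) antibody-id tuples with no self
    pairs and no duplicates; ``universe`` is the set of antibody ids
    eligible for evaluation (by default, those appearing in >=1 pair).
    """

    pairs: frozenset[tuple[str, str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        cleaned = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self pair {a!r}")
            cleaned.add(canonical_pair(a, b))
        self.pairs = frozenset(cleaned)
        if not self.universe:
            self.universe = frozenset(x for p in self.pairs for x in p)
        else:
            self.universe = frozenset(self.universe)
            stray = {x for p in self.pairs for x in p} - self.universe
            if stray:
                raise ValueError(f"pairs reference antibodies outside universe: {sorted(stray)}")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], universe: Iterable[str] = ()) -> "GoldStandardNetwork":
        pairs = frozenset(
            canonical_pair(a, b) for a, b in edges if a != b
        )
        return cls(pairs=pairs, universe=frozenset(universe))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.pairs

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def density(self) -> float:
        """Fraction of realized pairs among all non-self pairs of the universe."""
        n = len(self.universe)
        total = n * (n - 1) // 2
        if total == 0:
            return float("nan")
        return len(self.pairs) / total
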