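"""Gene-list collections, their hierarchy, and the interaction-strength mapping.

Discovery-set interactions (antibody pairs) are reduced to gene sets via the
antibody annotation and matched against a collection of gene lists (GMT
style).  A match contributes the absolute consensus edge weight penalized
(divided) by the gene-list size; per gene list and cohort the mean over
matched interactions is the "average interaction strength".  Gene lists live
in a rooted hierarchy (a DAG: a child may have several parents) and every
list can be traced to the top-level processes it descends from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

from .data import canonical_pair

if TYPE_CHECKING:  # pragma: no cover
    from .consensus import DiscoverySet

__all__ = [
    "GeneListCollection",
    "HierarchyIndex",
    "InteractionStrengthMatrix",
    "trace_top_level",
    "map_interactions",
    "matches_by_module_group",
]


@dataclass
class GeneListCollection:
    """Named gene sets, GMT-style: id -> frozenset of gene symbols."""

    lists: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lid, genes in self.lists.items():
            if not genes:
                raise ValueError(f"gene list {lid!r} is empty")
            self.lists[lid] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.lists)

    def __getitem__(self, lid: str) -> frozenset[str]:
        return self.lists[lid]

    def ids(self) -> list[str]:
        return list(self.lists)


class HierarchyIndex:
    """Parent relation over gene-list ids.

    The relation must be acyclic; a list without parents is top-level.
    ``depth`` is the longest distance to a root (roots have depth 0).
    """

    def __init__(self, relations: Iterable[tuple[str, str]], all_ids: Iterable[str]):
        self.parents: dict[str, set[str]] = {lid: set() for lid in all_ids}
        for parent, child in relations:
            if parent not in self.parents or child not in self.parents:
                warnings.warn(f"relation ({parent!r}, {child!r}) references an unknown id; dropped")
                continue
            self.parents[child].add(parent)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0=visiting, 1=done
        stack_path: list[str] = []

        def visit(node: str) -> None:
            state[node] = 0
            stack_path.append(node)
            for p in sorted(self.parents[node]):
                if state.get(p) == 0:
                    cyc = stack_path[stack_path.index(p):] + [p]
                    raise ValueError(f"cycle in hierarchy: {' -> '.join(cyc)}")
                if p not in state:
                    visit(p)
            stack_path.pop()
            state[node] = 1

        for lid in self.parents:
            if lid not in state:
                visit(lid)

    @property
    def top_level(self) -> frozenset[str]:
        return frozenset(lid for lid, ps in self.parents.items() if not ps)

    def depth(self, list_id: str) -> int:
        ps = self.parents[list_id]
        if not ps:
            return 0
        return 1 + max(self.depth(p) for p in ps)


def trace_top_level(list_id: str, hierarchy: HierarchyIndex) -> frozenset[str]:
    """All top-level (root) lists reachable from ``list_id`` via parent links."""
    if list_id not in hierarchy.parents:
        raise KeyError(f"unknown gene list {list_id!r}")
    roots: set[str] = set()
    seen: set[str] = set()
    stack = [list_id]
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        ps = hierarchy.parents[node]
        if not ps:
            roots.add(node)
        else:
            stack.extend(ps)
    return frozenset(roots)


@dataclass
class InteractionStrengthMatrix:
    """Gene lists x cohorts matrix of average interaction strengths.

    ``strength`` cells are NaN where no interaction matched (missing, not
    zero).  ``counts`` holds the number of matched interactions per cell and
    ``matches`` the matched pairs themselves, for downstream breakdowns.
    """

    strength: pd.DataFrame
    counts: pd.DataFrame
    matches: dict[str, dict[str, list[tuple[str, str]]]]  # cohort -> list id -> pairs

    @property
    def gene_lists(self) -> list[str]:
        return list(self.strength.index)

    @property
    def cohorts(self) -> list[str]:
        return list(self.strength.columns)


def map_interactions(
    discovery: "DiscoverySet",
    annotation: pd.DataFrame,
    gene_lists: GeneListCollection,
    signed: bool = False,
) -> InteractionStrengthMatrix:
    """Map significant interactions to gene lists, per cohort.

    For each cohort, iterate its significant pairs; reduce each pair to the
    gene sets of its two antibodies; skip pairs whose gene sets intersect
    (a self-interaction at the gene level); a gene list matches when both
    sets hit it, contributing |consensus weight| divided by the list size
    (the signed weight if ``signed``).  Cell value = mean of contributions.
    """
    missing = {a for p in discovery.pairs for a in p} - set(annotation.index)
    if missing:
        raise ValueError(f"antibodies without annotation: {sorted(missing)}")

    list_ids = gene_lists.ids()
    cohorts = list(discovery.cohorts)
    strength = pd.DataFrame(np.nan, index=list_ids, columns=cohorts, dtype=float)
    counts = pd.DataFrame(0, index=list_ids, columns=cohorts, dtype=int)
    matches: dict[str, dict[str, list[tuple[str, str]]]] = {c: {} for c in cohorts}

    gene_sets = {ab: frozenset(annotation.loc[ab, "genes"]) for ab in annotation.index}

    for cohort in cohorts:
        sig_pairs = [p for p in discovery.pairs if discovery.significant.at[p, cohort]]
        contrib: dict[str, list[float]] = {}
        for pair in sig_pairs:
            a, b = pair
            set1, set2 = gene_sets[a], gene_sets[b]
            if set1 & set2:
                continue  # gene-level self interaction
            w = discovery.weights.at[pair, cohort]
            val = w if signed else abs(w)
            for lid in list_ids:
                genes = gene_lists[lid]
                if (set1 & genes) and (set2 & genes):
                    contrib.setdefault(lid, []).append(val / len(genes))
                    matches[cohort].setdefault(lid, []).append(pair)
        for lid, vals in contrib.items():
            strength.loc[lid, cohort] = float(np.mean(vals))
            counts.loc[lid, cohort] = len(vals)

    return InteractionStrengthMatrix(strength=strength, counts=counts, matches=matches)


def matches_by_module_group(
    matrix: InteractionStrengthMatrix,
    discovery: "DiscoverySet",
    groups: Mapping[tuple[str, str], str],
    module_assignment: Mapping[str, int],
) -> pd.DataFrame:
    """Per-list matched-interaction counts broken down by edge group and module.

    Counts are averaged over cohorts.  Module tracks count only intra-module
    matched interactions (both antibodies in the same module), so they may be
    zero when the matching interactions are inter-module.
    """
    group_names = sorted(set(groups.values()))
    module_ids = sorted(set(module_assignment.values()))
    cols = [f"group:{g}" for g in group_names] + [f"module:{m}" for m in module_ids]
    out = pd.DataFrame(0.0, index=matrix.gene_lists, columns=cols)
    n_cohorts = len(matrix.cohorts)
    for cohort in matrix.cohorts:
        for lid, pairs in matrix.matches[cohort].items():
            for pair in pairs:
                pair = canonical_pair(*pair)
                g = groups.get(pair)
                if g is not None:
                    out.loc[lid, f"group:{g}"] += 1.0
                a, b = pair
                ma, mb = module_assignment.get(a), module_assignment.get(b)
                if ma is not None and ma == mb:
                    out.loc[lid, f"module:{ma}"] += 1.0
    return out / n_cohorts
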