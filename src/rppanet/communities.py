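"""Edge groups, community-detection consensus, and module statistics.

Discovery-set edges are clustered (Ward linkage, Euclidean distance) on
their per-cohort consensus-weight vectors into positive-dominant,
negative-dominant and heterogeneous groups.  The discovery-set graph is
partitioned by five community-detection algorithms (fast-greedy, spin-glass,
multilevel, infomap, walktrap); per antibody pair the fraction of algorithms
co-assigning the pair yields a consensus frequency matrix in
{0, 0.2, 0.4, 0.6, 0.8, 1}, which is itself Ward-clustered into consensus
modules.  Per-module statistics mirror the standard network summary:
intra-module edge counts split by group, antibody counts split by
phosphospecificity, average degree 2E/N, and the top intra-module hubs.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .consensus import DiscoverySet
from .data import canonical_pair

__all__ = [
    "EdgeGroupLabels",
    "ModuleConsensus",
    "classify_edge_groups",
    "detect_communities",
    "cut_consensus_modules",
    "module_statistics",
    "newman_modularity",
    "FIVE_ALGORITHMS",
]

FIVE_ALGORITHMS = ("fastgreedy", "spinglass", "multilevel", "infomap", "walktrap")

POSITIVE = "positive_dominant"
NEGATIVE = "negative_dominant"
HETEROGENEOUS = "heterogeneous"


@dataclass
class EdgeGroupLabels:
    """Group label per discovery pair plus per-group summary statistics."""

    labels: pd.Series  # MultiIndex pair -> group name
    summary: pd.DataFrame  # group -> size, mean_weight, mean_recurrence

    def __getitem__(self, pair: tuple[str, str]) -> str:
        return self.labels.loc[canonical_pair(*pair)]

    def as_dict(self) -> dict[tuple[str, str], str]:
        return {tuple(p): g for p, g in self.labels.items()}


def classify_edge_groups(discovery: DiscoverySet, n_groups: int = 3) -> EdgeGroupLabels:
    """Ward/Euclidean clustering of edge weight-vectors into signed groups.

    Clusters are labeled by mean pan-cancer weight: the highest-mean cluster
    is positive dominant, the lowest negative dominant, everything else
    heterogeneous.
    """
    if len(discovery) == 0:
        raise ValueError("discovery set is empty")
    if n_groups > len(discovery):
        raise ValueError("more groups than discovery pairs")
    V = discovery.weights.to_numpy()
    if len(discovery) == 1 or n_groups == 1:
        raw = np.ones(len(discovery), dtype=int)
    else:
        Z = linkage(pdist(V, metric="euclidean"), method="ward")
        raw = fcluster(Z, t=n_groups, criterion="maxclust")
    pan_weight = discovery.pan_cancer_weight.to_numpy()
    cluster_ids = sorted(set(raw))
    means = {c: pan_weight[raw == c].mean() for c in cluster_ids}
    name_of: dict[int, str] = {c: HETEROGENEOUS for c in cluster_ids}
    if len(cluster_ids) >= 2:
        name_of[max(cluster_ids, key=lambda c: means[c])] = POSITIVE
        name_of[min(cluster_ids, key=lambda c: means[c])] = NEGATIVE
    labels = pd.Series([name_of[c] for c in raw], index=discovery.weights.index, name="group")

    rec = discovery.recurrence
    rows = []
    for g in sorted(set(labels)):
        sel = labels == g
        rows.append(
            {
                "group": g,
                "size": int(sel.sum()),
                "mean_weight": float(discovery.pan_cancer_weight[sel].mean()),
                "mean_recurrence": float(rec[sel].mean()),
            }
        )
    return EdgeGroupLabels(labels=labels, summary=pd.DataFrame(rows).set_index("group"))


@dataclass
class ModuleConsensus:
    """Five-algorithm community-detection consensus.

    ``frequency[i, j]`` = (number of algorithms co-assigning antibodies i
    and j) / (number of algorithms used); symmetric, unit diagonal.
    """

    antibodies: list[str]
    frequency: np.ndarray
    assignments: pd.DataFrame  # antibodies x algorithms
    modularity: pd.Series  # algorithm -> Newman modularity
    n_algorithms: int

    def frequency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frequency, index=self.antibodies, columns=self.antibodies)


def _discovery_graph(discovery: DiscoverySet, weighted: bool = False) -> ig.Graph:
    antibodies = discovery.antibodies
    index = {a: i for i, a in enumerate(antibodies)}
    edges = [(index[a], index[b]) for a, b in discovery.pairs]
    g = ig.Graph(n=len(antibodies), edges=edges)
    g.vs["name"] = antibodies
    if weighted:
        g.es["weight"] = [abs(w) for w in discovery.pan_cancer_weight.to_numpy()]
    return g


def _run_algorithm(g: ig.Graph, name: str, seed: int, weights=None) -> list[int]:
    random.seed(seed)  # igraph's stochastic algorithms draw from Python's RNG
    if name == "fastgreedy":
        return g.community_fastgreedy(weights=weights).as_clustering().membership
    if name == "multilevel":
        return g.community_multilevel(weights=weights).membership
    if name == "infomap":
        return g.community_infomap(edge_weights=weights).membership
    if name == "walktrap":
        return g.community_walktrap(weights=weights).as_clustering().membership
    if name == "spinglass":
        # spin-glass requires a connected graph: run per component
        membership = [0] * g.vcount()
        offset = 0
        for comp in g.connected_components():
            sub = g.subgraph(comp)
            if sub.vcount() == 1:
                local = [0]
            else:
                sub_w = sub.es["weight"] if weights is not None else None
                local = sub.community_spinglass(weights=sub_w).membership
            for v, m in zip(comp, local):
                membership[v] = offset + m
            offset += max(local) + 1
        return membership
    raise KeyError(f"unknown community-detection algorithm {name!r}")


def detect_communities(
    discovery: DiscoverySet,
    algorithms: tuple[str, ...] = FIVE_ALGORITHMS,
    seed: int = 0,
    weighted: bool = False,
) -> ModuleConsensus:
    """Partition the discovery-set graph with each algorithm and build the
    co-assignment frequency matrix.

    The graph is unweighted by default (|pan-cancer weight| when
    ``weighted``).  An algorithm that fails is dropped with a warning and
    the frequency denominator adjusted.
    """
    g = _discovery_graph(discovery, weighted=weighted)
    w = g.es["weight"] if weighted else None
    memberships: dict[str, list[int]] = {}
    modularity: dict[str, float] = {}
    for name in algorithms:
        try:
            memb = _run_algorithm(g, name, seed=seed, weights=w)
        except Exception as err:
            warnings.warn(f"community algorithm {name!r} failed ({err}); dropped")
            continue
        memberships[name] = memb
        modularity[name] = float(g.modularity(memb, weights=w))
    if not memberships:
        raise ValueError("every community-detection algorithm failed")

    antibodies = g.vs["name"]
    n = len(antibodies)
    freq = np.zeros((n, n))
    for memb in memberships.values():
        m = np.asarray(memb)
        freq += (m[:, None] == m[None, :]).astype(float)
    freq /= len(memberships)
    np.fill_diagonal(freq, 1.0)

    assignments = pd.DataFrame(memberships, index=antibodies)
    return ModuleConsensus(
        antibodies=list(antibodies),
        frequency=freq,
        assignments=assignments,
        modularity=pd.Series(modularity, name="modularity"),
        n_algorithms=len(memberships),
    )


def cut_consensus_modules(consensus: ModuleConsensus, n_modules: int = 6) -> pd.Series:
    """Ward/Euclidean clustering of frequency-matrix rows into modules.

    Module ids are 1..n_modules ordered by decreasing size.
    """
    n = len(consensus.antibodies)
    if n_modules > n:
        raise ValueError("more modules than antibodies")
    if n_modules == 1 or n == 1:
        raw = np.ones(n, dtype=int)
    else:
        Z = linkage(pdist(consensus.frequency, metric="euclidean"), method="ward")
        raw = fcluster(Z, t=n_modules, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    return pd.Series([relabel[c] for c in raw], index=consensus.antibodies, name="module")


def newman_modularity(g: ig.Graph, membership: list[int]) -> float:
    """Newman modularity Q = sum_c (e_c/m - (d_c/2m)^2), computed directly."""
    m = g.ecount()
    if m == 0:
        return 0.0
    deg = g.degree()
    q = 0.0
    for c in set(membership):
        nodes = [v for v in range(g.vcount()) if membership[v] == c]
        node_set = set(nodes)
        e_c = sum(1 for e in g.es if e.source in node_set and e.target in node_set)
        d_c = sum(deg[v] for v in nodes)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def module_statistics(
    assignment: pd.Series,
    discovery: DiscoverySet,
    groups: EdgeGroupLabels,
    annotation: pd.DataFrame,
    n_hubs: int = 3,
) -> pd.DataFrame:
    """Per-module summary over intra-module interactions only.

    Per module: edge counts split by group; antibody counts split by
    phosphospecificity (only antibodies with >=1 intra-module edge are
    counted); average degree 2E/N; and the ``n_hubs`` highest intra-module-
    degree antibodies with their per-group edge counts.
    """
    group_of = groups.as_dict()
    module_ids = sorted(assignment.unique())
    rows = []
    for mod in module_ids:
        members = set(assignment.index[assignment == mod])
        intra = [p for p in discovery.pairs if p[0] in members and p[1] in members]
        by_group = {POSITIVE: 0, NEGATIVE: 0, HETEROGENEOUS: 0}
        degree: dict[str, int] = {}
        hub_groups: dict[str, dict[str, int]] = {}
        for p in intra:
            gname = group_of.get(p, HETEROGENEOUS)
            by_group[gname] += 1
            for a in p:
                degree[a] = degree.get(a, 0) + 1
                hub_groups.setdefault(a, {POSITIVE: 0, NEGATIVE: 0, HETEROGENEOUS: 0})[gname] += 1
        connected = sorted(degree)
        n_edges = len(intra)
        n_ab = len(connected)
        phospho = sum(bool(annotation.loc[a, "phosphospecific"]) for a in connected)
        hubs = sorted(connected, key=lambda a: (-degree[a], a))[:n_hubs]
        hub_desc = "; ".join(
            f"{a} ({degree[a]} total; "
            f"{hub_groups[a][POSITIVE]},{hub_groups[a][NEGATIVE]},{hub_groups[a][HETEROGENEOUS]})"
            for a in hubs
        )
        rows.append(
            {
                "module": mod,
                "n_edges": n_edges,
                "edges_positive": by_group[POSITIVE],
                "edges_negative": by_group[NEGATIVE],
                "edges_heterogeneous": by_group[HETEROGENEOUS],
                "n_antibodies": n_ab,
                "n_nonphospho": n_ab - phospho,
                "n_phospho": phospho,
                "avg_degree": (2.0 * n_edges / n_ab) if n_ab else 0.0,
                "hubs": hub_desc,
            }
        )
    return pd.DataFrame(rows).set_index("module")
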