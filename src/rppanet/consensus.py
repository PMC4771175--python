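"""Consensus networks over a high-performing method set.

Per cohort, the consensus edge rank is the mean of the tie-averaged ranks
from the selected methods (a nonparametric proxy for significance: method
p-values are unavailable or not independently combinable), and the
consensus edge weight is the mean of the per-method weights after min-max
scaling of |weight| to [0,1] (so mutual-information magnitudes cannot
dominate), signed by the majority sign among the signed methods.  A global
rank threshold is chosen at the inflection of the summed explained variance
of the first three principal components as the threshold is swept; edges
beating the threshold in at least one cohort form the *discovery set*, with
a per-edge recurrence count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .inference import EdgeRanking, WeightedNetwork

__all__ = [
    "CohortConsensus",
    "DiscoverySet",
    "build_consensus",
    "select_rank_threshold",
    "pc_variance_series",
    "find_inflection",
    "build_discovery_set",
    "cohort_similarity",
    "DEFAULT_THRESHOLD_CANDIDATES",
]

DEFAULT_THRESHOLD_CANDIDATES = tuple(range(25, 2001, 25))


@dataclass
class CohortConsensus:
    """Per-pair consensus rank and signed consensus weight for one cohort."""

    rank: pd.Series  # MultiIndex (antibody1, antibody2) -> mean rank
    weight: pd.Series  # same index -> signed scaled mean weight
    method_set: tuple[str, ...]

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.rank.index)

    def significant_pairs(self, threshold: float) -> list[tuple[str, str]]:
        return list(self.rank.index[self.rank < threshold])


def build_consensus(
    rankings: dict[str, EdgeRanking],
    networks: dict[str, WeightedNetwork],
    method_set: list[str] | tuple[str, ...],
) -> CohortConsensus:
    """Average ranks and scaled weights over ``method_set`` for one cohort."""
    if not method_set:
        raise ValueError("method_set is empty")
    missing = [m for m in method_set if m not in rankings or m not in networks]
    if missing:
        raise KeyError(f"methods without fitted results: {missing}")
    ref_pairs = rankings[method_set[0]].pairs
    index = pd.MultiIndex.from_tuples(ref_pairs, names=["antibody1", "antibody2"])

    rank_mat = np.zeros((len(method_set), len(ref_pairs)))
    scaled = np.zeros_like(rank_mat)
    signs = []
    for k, m in enumerate(method_set):
        r = rankings[m]
        if r.pairs != ref_pairs:
            raise ValueError(f"method {m!r} does not share the antibody universe")
        rank_mat[k] = r.avg_rank
        w = networks[m].edge_weights().to_numpy()
        a = np.abs(w)
        span = a.max() - a.min()
        scaled[k] = (a - a.min()) / span if span > 0 else np.zeros_like(a)
        if networks[m].signed:
            signs.append(np.sign(w))

    mean_rank = rank_mat.mean(axis=0)
    magnitude = scaled.mean(axis=0)
    if signs:
        sign_sum = np.sum(signs, axis=0)
        sign = np.where(sign_sum < 0, -1.0, 1.0)  # zero-sum ties -> positive
    else:
        sign = np.ones_like(magnitude)
    return CohortConsensus(
        rank=pd.Series(mean_rank, index=index, name="consensus_rank"),
        weight=pd.Series(sign * magnitude, index=index, name="consensus_weight"),
        method_set=tuple(method_set),
    )


def _union_weight_matrix(consensus: dict[str, CohortConsensus], threshold: float) -> pd.DataFrame:
    """Edges (significant in >=1 cohort) x cohorts matrix of consensus weights."""
    cohorts = list(consensus)
    union: set = set()
    for c in cohorts:
        union.update(consensus[c].significant_pairs(threshold))
    pairs = sorted(union)
    if not pairs:
        return pd.DataFrame(index=pd.MultiIndex.from_tuples([], names=["antibody1", "antibody2"]), columns=cohorts, dtype=float)
    index = pd.MultiIndex.from_tuples(pairs, names=["antibody1", "antibody2"])
    mat = pd.DataFrame(
        {c: consensus[c].weight.reindex(index) for c in cohorts}, index=index
    )
    return mat


def pc_variance_series(
    consensus: dict[str, CohortConsensus],
    candidates: tuple[int, ...],
    n_pcs: int = 3,
) -> np.ndarray:
    """Summed explained-variance percentage of the first ``n_pcs`` PCs per candidate.

    For each candidate T the union edges x cohorts weight matrix (pairs with
    consensus rank < T in >=1 cohort) is decomposed with cohorts as
    variables.
    """
    series = []
    for T in candidates:
        mat = _union_weight_matrix(consensus, T)
        if mat.shape[0] < 2:
            series.append(0.0)
            continue
        k = min(n_pcs, mat.shape[1], mat.shape[0])
        pca = PCA(n_components=k)
        pca.fit(mat.to_numpy())
        series.append(float(pca.explained_variance_ratio_[:n_pcs].sum() * 100.0))
    return np.asarray(series)


def find_inflection(
    series: np.ndarray, candidates: tuple[int, ...], smooth_window: int = 3
):
    """Candidate at the largest-magnitude discrete second difference.

    The series is smoothed with a centered moving average (edge-padded)
    first.  A degenerate series (flat or exactly linear) yields the median
    candidate with a warning.  Returns ``(threshold, diagnostics)``.
    """
    series = np.asarray(series, dtype=float)
    if smooth_window > 1 and len(series) >= smooth_window:
        # valid-mode smoothing: no edge padding, which would fabricate
        # curvature at the boundaries of the sweep
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(series, kernel, mode="valid")
        offset = smooth_window // 2
    else:
        smoothed = series.copy()
        offset = 0

    d2 = np.zeros_like(smoothed)
    if len(smoothed) >= 3:
        d2[1:-1] = smoothed[2:] - 2 * smoothed[1:-1] + smoothed[:-2]
    smoothed_full = np.full(len(series), np.nan)
    smoothed_full[offset : offset + len(smoothed)] = smoothed
    d2_full = np.zeros(len(series))
    d2_full[offset : offset + len(smoothed)] = d2
    diagnostics = pd.DataFrame(
        {"threshold": candidates, "ev_first_pcs": series, "smoothed": smoothed_full, "second_diff": d2_full}
    )
    if len(smoothed) < 3 or np.abs(d2).max() < 1e-9:
        warnings.warn("degenerate variance series; returning the median candidate")
        return int(candidates[len(candidates) // 2]), diagnostics
    return int(candidates[int(np.argmax(np.abs(d2))) + offset]), diagnostics


def select_rank_threshold(
    consensus: dict[str, CohortConsensus],
    candidates: tuple[int, ...] = DEFAULT_THRESHOLD_CANDIDATES,
    n_pcs: int = 3,
    smooth_window: int = 3,
):
    """Pick the consensus-rank threshold at the inflection of the PC-variance sweep.

    Composes :func:`pc_variance_series` and :func:`find_inflection`; returns
    ``(threshold, diagnostics)`` where the diagnostics table carries the full
    sweep for inspection.
    """
    if len(consensus) < 2:
        raise ValueError("need at least 2 cohorts")
    candidates = tuple(candidates)
    series = pc_variance_series(consensus, candidates, n_pcs=n_pcs)
    return find_inflection(series, candidates, smooth_window=smooth_window)


@dataclass
class DiscoverySet:
    """Union of per-cohort significant edges with recurrence annotation.

    ``weights`` carries the full consensus weight of every discovery pair in
    every cohort (including cohorts where the pair missed the threshold);
    ``significant`` is the per-cohort boolean threshold mask whose row sums
    are the recurrences.
    """

    weights: pd.DataFrame  # pairs x cohorts
    significant: pd.DataFrame  # pairs x cohorts, bool
    threshold: float

    def __post_init__(self) -> None:
        if not self.weights.index.equals(self.significant.index):
            raise ValueError("weights and significance masks must align")
        if not (self.significant.sum(axis=1) >= 1).all():
            raise ValueError("every discovery pair must be significant somewhere")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.weights.index)

    @property
    def cohorts(self) -> list[str]:
        return list(self.weights.columns)

    @property
    def antibodies(self) -> list[str]:
        return sorted({a for p in self.pairs for a in p})

    @property
    def recurrence(self) -> pd.Series:
        return self.significant.sum(axis=1).rename("recurrence")

    @property
    def pan_cancer_weight(self) -> pd.Series:
        return self.weights.mean(axis=1).rename("pan_cancer_weight")

    def __len__(self) -> int:
        return len(self.weights)


def build_discovery_set(consensus: dict[str, CohortConsensus], threshold: float) -> DiscoverySet:
    """Union of significant pairs across cohorts at the given rank threshold."""
    mat = _union_weight_matrix(consensus, threshold)
    if mat.empty:
        raise ValueError(f"no pair is significant at threshold {threshold}")
    sig = pd.DataFrame(
        {c: consensus[c].rank.reindex(mat.index) < threshold for c in consensus}, index=mat.index
    )
    return DiscoverySet(weights=mat, significant=sig, threshold=threshold)


def cohort_similarity(discovery: DiscoverySet, n_groups: int = 4):
    """Cohort-level similarity of significant edge sets and weight profiles.

    Returns ``(jaccard, pc_scores, labels)``: the cohorts x cohorts Jaccard
    matrix of significant-pair sets, PCA scores of the cohorts-as-vectors
    weight matrix, and Ward-linkage/Euclidean cluster labels on the same
    vectors.
    """
    cohorts = discovery.cohorts
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    sets = {c: frozenset(discovery.significant.index[discovery.significant[c]]) for c in cohorts}
    J = np.ones((len(cohorts), len(cohorts)))
    for i, a in enumerate(cohorts):
        for j, b in enumerate(cohorts):
            if i < j:
                u = len(sets[a] | sets[b])
                J[i, j] = J[j, i] = (len(sets[a] & sets[b]) / u) if u else 1.0
    jaccard = pd.DataFrame(J, index=cohorts, columns=cohorts)

    V = discovery.weights.to_numpy().T  # cohorts x edges
    k = min(len(cohorts), V.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(V)
    pc_scores = pd.DataFrame(scores, index=cohorts, columns=[f"PC{i + 1}" for i in range(k)])

    Z = linkage(pdist(V, metric="euclidean"), method="ward")
    labels = pd.Series(
        fcluster(Z, t=min(n_groups, len(cohorts)), criterion="maxclust"), index=cohorts, name="cluster"
    )
    return jaccard, pc_scores, labels
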