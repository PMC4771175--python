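"""Precision-recall benchmarking and cross-cohort method comparison.

Inferred edge rankings are traversed most-significant-first against a
gold-standard edge set; precision at cutoff t is TP(t)/t and recall is
TP(t)/|gold|.  Methods are compared by the area under the PR curve
restricted to a low-recall window (default recall in [0, 0.1]): beyond that
window precision collapses toward the gold density and methods become
indistinguishable.  Grid-parameterized methods are optimized by exhaustive
grid search on that limited-recall AUPR.  Cross-cohort scores are the sum of
per-cohort AUPRs and the sum of per-cohort AUPR ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .data import GoldStandardNetwork
from .inference import EdgeRanking, default_grid, fit_method, rank_edges

__all__ = [
    "PRCurve",
    "pr_curve",
    "aupr",
    "optimize_params",
    "rank_methods",
    "top_k_methods",
    "method_similarity",
    "DEFAULT_RECALL_MAX",
]

DEFAULT_RECALL_MAX = 0.1


@dataclass
class PRCurve:
    """Precision-recall curve over cumulatively growing top-edge sets."""

    recall: np.ndarray
    precision: np.ndarray
    method: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.recall = np.asarray(self.recall, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        if self.recall.shape != self.precision.shape:
            raise ValueError("recall and precision must have the same length")
        if np.any(np.diff(self.recall) < 0):
            raise ValueError("recall must be nondecreasing")


def pr_curve(ranking: EdgeRanking, gold: GoldStandardNetwork) -> PRCurve:
    """PR curve of a ranking against the gold standard.

    Pairs involving antibodies outside the gold universe are excluded before
    traversal, so adding antibodies with no gold edges cannot change the
    curve.
    """
    if not gold.pairs:
        raise ValueError("gold standard is empty")
    universe = gold.universe
    hits = []
    for pair in ranking.ordered_pairs():
        a, b = pair
        if a in universe and b in universe:
            hits.append(1.0 if pair in gold else 0.0)
    if not hits:
        raise ValueError("no ranked pair falls inside the gold universe")
    tp = np.cumsum(hits)
    t = np.arange(1, len(hits) + 1)
    return PRCurve(recall=tp / gold.n_pairs, precision=tp / t, method=ranking.method)


def aupr(curve: PRCurve, recall_max: float = DEFAULT_RECALL_MAX) -> float:
    """Trapezoidal area under the PR curve on recall in [0, recall_max].

    The curve is anchored at (0, precision of the first point) and truncated
    at ``recall_max`` with linear interpolation; the result is bounded by
    ``recall_max``.
    """
    if not 0 < recall_max <= 1:
        raise ValueError("recall_max must be in (0, 1]")
    r = np.concatenate([[0.0], curve.recall])
    p = np.concatenate([[curve.precision[0]], curve.precision])
    if r[-1] <= recall_max:
        return float(np.trapezoid(p, r))
    k = int(np.searchsorted(r, recall_max, side="left"))
    if r[k] == recall_max:
        r_cut, p_cut = r[: k + 1], p[: k + 1]
    else:
        frac = (recall_max - r[k - 1]) / (r[k] - r[k - 1])
        p_interp = p[k - 1] + frac * (p[k] - p[k - 1])
        r_cut = np.concatenate([r[:k], [recall_max]])
        p_cut = np.concatenate([p[:k], [p_interp]])
    return float(np.trapezoid(p_cut, r_cut))


def optimize_params(
    method: str,
    grid: list[dict] | None,
    cohort: pd.DataFrame,
    gold: GoldStandardNetwork,
    recall_max: float = DEFAULT_RECALL_MAX,
    seed: int = 0,
    mi_matrix=None,
):
    """Exhaustive grid search maximizing limited-recall AUPR.

    Returns ``(best_params, best_aupr, best_fit, table)`` where ``best_fit``
    is the ``(network, ranking)`` pair at the optimum and ``table`` records
    the AUPR of every grid cell.  Ties break to the first cell in grid
    order.  Methods without user-specified parameters use the single empty
    configuration.
    """
    if grid is None:
        grid = default_grid(method)
    if not grid:
        raise ValueError("parameter grid is empty")
    rows, failures = [], []
    best = None
    for cell in grid:
        try:
            net = fit_method(method, cohort, cell, seed=seed, mi_matrix=mi_matrix)
            ranking = rank_edges(net)
            score = aupr(pr_curve(ranking, gold), recall_max)
        except Exception as err:
            failures.append((cell, str(err)))
            rows.append({"params": cell, "aupr": np.nan})
            continue
        rows.append({"params": cell, "aupr": score})
        if best is None or score > best[1]:
            best = (cell, score, (net, ranking))
    if best is None:
        detail = "; ".join(f"{c}: {msg}" for c, msg in failures)
        raise ValueError(f"all grid cells failed for {method}: {detail}")
    table = pd.DataFrame(rows)
    return best[0], best[1], best[2], table


def rank_methods(aupr_table: pd.DataFrame) -> pd.DataFrame:
    """Score methods across cohorts.

    ``aupr_table`` is methods x cohorts.  Returns per-method ``overall_aupr``
    (sum of AUPRs), ``overall_aupr_rank`` (sum of per-cohort ranks where
    rank 1 = best AUPR, tie-averaged), plus the per-cohort ranks.
    """
    if aupr_table.isna().any().any():
        raise ValueError("AUPR table must be complete")
    ranks = aupr_table.rank(axis=0, ascending=False, method="average")
    out = pd.DataFrame(
        {
            "overall_aupr": aupr_table.sum(axis=1),
            "overall_aupr_rank": ranks.sum(axis=1),
        }
    )
    return pd.concat([out, ranks.add_prefix("rank_")], axis=1)


def top_k_methods(scores: pd.DataFrame, k: int = 6) -> list[str]:
    """Methods in the top k by BOTH overall AUPR and overall AUPR rank.

    Falls back to the top k by overall AUPR rank when the intersection has
    fewer than two members (the two criteria usually agree).
    """
    by_aupr = scores.sort_values("overall_aupr", ascending=False).index[:k]
    by_rank = scores.sort_values("overall_aupr_rank", ascending=True).index[:k]
    both = [m for m in by_rank if m in set(by_aupr)]
    if len(both) < 2:
        warnings.warn("top-k criteria barely intersect; using overall AUPR rank")
        return list(by_rank)
    return both


def method_similarity(stacked: pd.DataFrame, n_clusters: int = 3):
    """Similarity structure of methods from stacked edge-weight vectors.

    ``stacked`` is methods x edges (edge weights from all cohorts stacked
    into one vector per method; MI-family weights enter unsigned, as
    produced).  Returns ``(spearman, pc_scores, explained_var, labels)``:
    the methods x methods Spearman matrix (constant vectors correlate 0,
    with a warning), PCA scores and explained-variance fractions of the
    centered matrix, and complete-linkage/Euclidean cluster labels computed
    on the rows of the correlation matrix.
    """
    methods = list(stacked.index)
    V = stacked.to_numpy(dtype=float)
    const = V.std(axis=1) == 0
    if const.any():
        warnings.warn(f"constant weight vector(s): {[m for m, c in zip(methods, const) if c]}")
    ranks = stats.rankdata(V, axis=1)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    rho[const, :] = 0.0
    rho[:, const] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.nan_to_num(rho)
    spearman = pd.DataFrame(rho, index=methods, columns=methods)

    n_pc = min(len(methods), V.shape[1])
    pca = PCA(n_components=n_pc)
    scores = pca.fit_transform(V - V.mean(axis=0, keepdims=True))
    pc_scores = pd.DataFrame(
        scores, index=methods, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    )
    explained = pd.Series(
        pca.explained_variance_ratio_, index=pc_scores.columns, name="explained_variance"
    )

    Z = linkage(pdist(rho, metric="euclidean"), method="complete")
    labels = pd.Series(
        fcluster(Z, t=min(n_clusters, len(methods)), criterion="maxclust"),
        index=methods,
        name="cluster",
    )
    return spearman, pc_scores, explained, labels
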