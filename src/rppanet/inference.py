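"""The 13 network-inference estimators.

Four families, all mapping a samples x antibodies matrix to a symmetric
weighted network over the antibodies:

* correlation — Pearson and Spearman sample correlation;
* partial correlation via inverse covariance — straight (pseudo-)inverse,
  Schafer-Strimmer shrinkage of the correlation matrix, and the graphical
  lasso (L1-penalized precision);
* partial correlation via node-wise regression — ridge, lasso, elastic net
  and partial least squares, with the penalty (or component count) chosen by
  inner cross-validated prediction error and the coefficient matrix
  symmetrized into partial correlations;
* mutual information — a k-nearest-neighbor (Kraskov-style) MI matrix
  post-processed by ARACNE (additive or multiplicative DPI pruning), CLR
  (row-background z-scores) or MRNET (max-relevance/min-redundancy forward
  selection).

Correlation and partial-correlation weights are signed; mutual-information
weights are nonnegative.  Edge significance is |weight|, summarized by
:func:`rank_edges`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import graphical_lasso
from sklearn.cross_decomposition import PLSRegression
from sklearn.feature_selection import mutual_info_regression
from sklearn.linear_model import ElasticNetCV, LassoCV, RidgeCV
from sklearn.model_selection import KFold

__all__ = [
    "WeightedNetwork",
    "EdgeRanking",
    "infer_correlation",
    "infer_parcor_inverse",
    "infer_parcor_regression",
    "symmetrize_coefficients",
    "estimate_mi",
    "infer_mi_network",
    "rank_edges",
    "fit_method",
    "METHODS",
    "MI_METHODS",
    "SIGNED_METHODS",
    "default_grid",
]

# Re-specified per-method search grids spanning the under- to
# over-regularization regimes (the original grids are not published).
PENALTY_GRID = tuple(np.logspace(-4, 2, 10))
L1_RATIOS = (0.25, 0.5, 0.75)
GLASSO_RHOS = tuple(np.round(np.logspace(-2, 0, 8), 6))
ARACNE_EPS = (0.0, 0.05, 0.1, 0.15, 0.2)
ARACNE_TAUS = (0.0, 0.05, 0.1, 0.15, 0.2)
DEFAULT_K_NEIGHBORS = 3
DEFAULT_CV_FOLDS = 5

METHODS = (
    "pearsoncor",
    "spearmancor",
    "simpleparcor",
    "genenet",
    "glasso",
    "ridgenet",
    "lassonet",
    "elasticnet",
    "plsnet",
    "aracne_a",
    "aracne_m",
    "clr",
    "mrnet",
)
MI_METHODS = frozenset({"aracne_a", "aracne_m", "clr", "mrnet"})
SIGNED_METHODS = frozenset(METHODS) - MI_METHODS


@dataclass
class WeightedNetwork:
    """Symmetric weighted network with zero diagonal.

    ``signed`` is False for the mutual-information family, whose weights are
    nonnegative; correlation and partial-correlation weights carry a sign.
    """

    antibody_ids: list[str]
    weights: np.ndarray
    signed: bool
    method: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = len(self.antibody_ids)
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (p, p):
            raise ValueError("weights shape mismatch")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        if not self.signed and (w < 0).any():
            raise ValueError("unsigned network cannot have negative weights")
        self.weights = w

    @property
    def n_antibodies(self) -> int:
        return len(self.antibody_ids)

    def pairs(self) -> list[tuple[str, str]]:
        """All C(p,2) unordered pairs, in matrix (i<j) order."""
        return list(combinations(self.antibody_ids, 2))

    def edge_weights(self) -> pd.Series:
        iu = np.triu_indices(self.n_antibodies, k=1)
        return pd.Series(
            self.weights[iu], index=pd.MultiIndex.from_tuples(self.pairs()), name=self.method
        )


@dataclass
class EdgeRanking:
    """Significance ranking of all pairs of a network.

    ``avg_rank`` holds tie-averaged ranks of |weight| (1 = most significant),
    aligned with ``pairs``; ``order`` is a deterministic traversal
    permutation (descending |weight|, ties broken by the lexicographic pair)
    used for precision-recall curves.
    """

    pairs: list[tuple[str, str]]
    avg_rank: np.ndarray
    order: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        m = len(self.pairs)
        if len(self.avg_rank) != m or len(self.order) != m:
            raise ValueError("ranking arrays must cover all pairs")

    def rank_series(self) -> pd.Series:
        return pd.Series(
            self.avg_rank, index=pd.MultiIndex.from_tuples(self.pairs), name=self.method
        )

    def ordered_pairs(self) -> list[tuple[str, str]]:
        return [self.pairs[k] for k in self.order]


def rank_edges(net: WeightedNetwork) -> EdgeRanking:
    """Rank all pairs by descending |weight|, tie-averaged."""
    pairs = net.pairs()
    iu = np.triu_indices(net.n_antibodies, k=1)
    absw = np.abs(net.weights[iu])
    avg_rank = stats.rankdata(-absw, method="average")
    order = np.array(sorted(range(len(pairs)), key=lambda k: (-absw[k], pairs[k])), dtype=int)
    return EdgeRanking(pairs=pairs, avg_rank=avg_rank, order=order, method=net.method)


# ---------------------------------------------------------------------------
# helpers


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"V{j + 1}" for j in range(X.shape[1])]

def _check_samples(X: np.ndarray, minimum: int = 3) -> None:
    if X.shape[0] < minimum:
        raise ValueError(f"need at least {minimum} samples, got {X.shape[0]}")

def _check_variance(X: np.ndarray, ids: list[str]) -> None:
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = ids[int(np.argmax(sd == 0))]
        raise ValueError(f"antibody {bad!r} has zero variance")

def _standardize(X: np.ndarray) -> np.ndarray:
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)

def _pcor_from_precision(P: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.abs(np.diag(P)))
    W = -P / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return np.clip((W + W.T) / 2.0, -1.0, 1.0)


# ---------------------------------------------------------------------------
# correlation family


def infer_correlation(X, variant: str = "pearson") -> WeightedNetwork:
    """Pearson or Spearman sample correlation network."""
    M, ids = _as_matrix(X)
    _check_samples(M)
    _check_variance(M, ids)
    if variant == "pearson":
        W = np.corrcoef(M, rowvar=False)
    elif variant == "spearman":
        ranks = stats.rankdata(M, axis=0)
        W = np.corrcoef(ranks, rowvar=False)
    else:
        raise ValueError(f"unknown correlation variant {variant!r}")
    np.fill_diagonal(W, 0.0)
    return WeightedNetwork(ids, W, signed=True, method=f"{variant}cor", params={})


# ---------------------------------------------------------------------------
# partial correlation via inverse covariance


def _shrunk_correlation(M: np.ndarray) -> tuple[np.ndarray, float]:
    """Schafer-Strimmer analytic shrinkage of the correlation matrix toward I."""
    n = M.shape[0]
    Z = _standardize(M)
    wbar = (Z.T @ Z) / n
    S2 = (Z**2).T @ (Z**2)
    var_r = n / (n - 1) ** 3 * (S2 - n * wbar**2)
    R = n / (n - 1) * wbar
    off = ~np.eye(R.shape[0], dtype=bool)
    denom = (R[off] ** 2).sum()
    lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))
    R_star = (1 - lam) * R + lam * np.eye(R.shape[0])
    return R_star, lam


def infer_parcor_inverse(X, variant: str = "simple", rho: float = 0.1) -> WeightedNetwork:
    """Partial correlation from an estimated precision matrix.

    ``simple``: pseudo-inverse of the sample covariance (no regularization;
    degrades when samples < ~2x antibodies).  ``shrinkage``: invert the
    analytically shrunk correlation matrix.  ``glasso``: L1-penalized
    maximum-likelihood precision at penalty ``rho``.
    In all cases ``w_ij = -P_ij / sqrt(P_ii * P_jj)``.
    """
    M, ids = _as_matrix(X)
    _check_samples(M)
    _check_variance(M, ids)
    params: dict = {}
    if variant == "simple":
        cov = np.cov(M, rowvar=False)
        P = np.linalg.pinv(cov)
    elif variant == "shrinkage":
        R_star, lam = _shrunk_correlation(M)
        P = np.linalg.inv(R_star)
        params["shrinkage_intensity"] = lam
    elif variant == "glasso":
        R = np.corrcoef(M, rowvar=False)
        try:
            _, P = graphical_lasso(R, alpha=float(rho), max_iter=200)
        except Exception as err:
            raise ValueError(f"graphical lasso failed to converge at rho={rho}: {err}") from err
        params["rho"] = float(rho)
    else:
        raise ValueError(f"unknown inverse-covariance variant {variant!r}")
    W = _pcor_from_precision(P)
    name = {"simple": "simpleparcor", "shrinkage": "genenet", "glasso": "glasso"}[variant]
    return WeightedNetwork(ids, W, signed=True, method=name, params=params)


# ---------------------------------------------------------------------------
# partial correlation via node-wise regression


def symmetrize_coefficients(B: np.ndarray) -> np.ndarray:
    """Partial correlations from a node-wise coefficient matrix.

    ``pc_ij = sign(B_ij) * sqrt(max(0, B_ij * B_ji))``: the geometric mean of
    the two directed coefficients when their signs agree, 0 on sign conflict.
    """
    prod = B * B.T
    W = np.where(prod > 0, np.sign(B) * np.sqrt(np.maximum(prod, 0.0)), 0.0)
    W = np.clip((W + W.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(W, 0.0)
    return W


def _pls_coefficients(Xo: np.ndarray, y: np.ndarray, max_components: int, cv: KFold) -> np.ndarray:
    """PLS regression coefficients with the component count chosen by CV MSE."""
    best_c, best_mse = 1, np.inf
    for c in range(1, max_components + 1):
        sse = 0.0
        for tr, te in cv.split(Xo):
            pls = PLSRegression(n_components=c, scale=False)
            pls.fit(Xo[tr], y[tr])
            resid = y[te] - pls.predict(Xo[te]).ravel()
            sse += float(resid @ resid)
        mse = sse / len(y)
        if mse < best_mse - 1e-12:
            best_mse, best_c = mse, c
    pls = PLSRegression(n_components=best_c, scale=False)
    pls.fit(Xo, y)
    return pls.coef_.ravel()


def infer_parcor_regression(
    X,
    variant: str = "ridge",
    penalties: tuple[float, ...] = PENALTY_GRID,
    l1_ratios: tuple[float, ...] = L1_RATIOS,
    max_components: int = 8,
    cv_folds: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
) -> WeightedNetwork:
    """Node-wise regression route to partial correlation.

    Each antibody is regressed on all others under the variant's penalty;
    the penalty (or PLS component count) is chosen per node by ``cv_folds``-
    fold cross-validated prediction error over the supplied grid.  The
    coefficient matrix B is symmetrized into partial correlations by
    ``pc_ij = sign(B_ij) * sqrt(max(0, B_ij * B_ji))`` — coefficients that
    disagree in sign yield weight 0.
    """
    M, ids = _as_matrix(X)
    _check_samples(M, minimum=max(5, cv_folds))
    _check_variance(M, ids)
    if variant in ("ridge", "lasso", "elasticnet") and len(penalties) == 0:
        raise ValueError("penalty grid is empty")
    Z = _standardize(M)
    p = Z.shape[1]
    penalties = [float(a) for a in penalties]
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    B = np.zeros((p, p))
    for j in range(p):
        others = [i for i in range(p) if i != j]
        Xo, y = Z[:, others], Z[:, j]
        if variant == "ridge":
            model = RidgeCV(alphas=penalties, cv=cv).fit(Xo, y)
            coef = model.coef_
        elif variant == "lasso":
            model = LassoCV(alphas=penalties, cv=cv, random_state=seed, max_iter=5000).fit(Xo, y)
            coef = model.coef_
        elif variant == "elasticnet":
            model = ElasticNetCV(
                alphas=penalties, l1_ratio=list(l1_ratios), cv=cv, random_state=seed, max_iter=5000
            ).fit(Xo, y)
            coef = model.coef_
        elif variant == "pls":
            coef = _pls_coefficients(Xo, y, min(max_components, p - 1), cv)
        else:
            raise ValueError(f"unknown regression variant {variant!r}")
        B[j, others] = coef
    W = symmetrize_coefficients(B)
    name = {"ridge": "ridgenet", "lasso": "lassonet", "elasticnet": "elasticnet", "pls": "plsnet"}[variant]
    return WeightedNetwork(ids, W, signed=True, method=name, params={"cv_folds": cv_folds})


# ---------------------------------------------------------------------------
# mutual information family


def estimate_mi(X, k_neighbors: int = DEFAULT_K_NEIGHBORS, seed: int = 0) -> np.ndarray:
    """Pairwise k-nearest-neighbor (Kraskov-style) mutual information matrix.

    Entries are in nats, clamped at 0; the diagonal is 0.
    """
    M, ids = _as_matrix(X)
    if k_neighbors >= M.shape[0]:
        raise ValueError("k_neighbors must be smaller than the number of samples")
    _check_variance(M, ids)
    p = M.shape[1]
    mi = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            val = mutual_info_regression(
                M[:, [i]], M[:, j], n_neighbors=k_neighbors, random_state=seed
            )[0]
            mi[i, j] = mi[j, i] = max(0.0, float(val))
    return mi


def _dpi_threshold(mi: np.ndarray) -> np.ndarray:
    """For each pair (i,j): max over k of min(MI_ik, MI_jk)."""
    p = mi.shape[0]
    mins = np.minimum(mi[:, None, :], mi[None, :, :])  # (i, j, k)
    k_idx = np.arange(p)
    mins[k_idx, :, k_idx] = -np.inf
    mins[:, k_idx, k_idx] = -np.inf
    return mins.max(axis=2)


def _clr(mi: np.ndarray) -> np.ndarray:
    p = mi.shape[0]
    off = ~np.eye(p, dtype=bool)
    mu = np.array([mi[i, off[i]].mean() for i in range(p)])
    sd = np.array([mi[i, off[i]].std() for i in range(p)])
    sd = np.where(sd == 0, 1.0, sd)
    z = (mi - mu[:, None]) / sd[:, None]  # z_i(ij) in row i
    z = np.maximum(z, 0.0)
    W = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(W, 0.0)
    return W


def _mrmr_scores(mi: np.ndarray, target: int) -> np.ndarray:
    """Forward max-relevance/min-redundancy selection scores for one target."""
    p = mi.shape[0]
    scores = np.zeros(p)
    candidates = [j for j in range(p) if j != target]
    selected: list[int] = []
    while candidates:
        if selected:
            obj = np.array(
                [mi[j, target] - mi[j, selected].mean() for j in candidates]
            )
        else:
            obj = np.array([mi[j, target] for j in candidates])
        k = int(np.argmax(obj))
        if selected and obj[k] <= 0:
            break
        scores[candidates[k]] = max(0.0, float(obj[k]))
        selected.append(candidates.pop(k))
    return scores


def infer_mi_network(
    mi_matrix: np.ndarray,
    variant: str = "aracne_a",
    eps: float = 0.0,
    tau: float = 0.0,
    antibody_ids: list[str] | None = None,
) -> WeightedNetwork:
    """Post-process a mutual-information matrix into an unsigned network.

    ``aracne_a``/``aracne_m`` prune, in every triplet, the weakest edge via
    the data-processing inequality with an additive (``eps``) or
    multiplicative (``tau``) tolerance; ``clr`` standardizes each MI value
    against its row backgrounds; ``mrnet`` scores pairs by forward
    max-relevance/min-redundancy selection, symmetrized by max.
    """
    mi = np.asarray(mi_matrix, dtype=float)
    p = mi.shape[0]
    if mi.shape != (p, p) or not np.allclose(mi, mi.T):
        raise ValueError("mi_matrix must be square and symmetric")
    if (mi < 0).any():
        raise ValueError("mi_matrix must be nonnegative")
    if eps < 0 or tau < 0:
        raise ValueError("eps and tau must be nonnegative")
    ids = antibody_ids or [f"V{j + 1}" for j in range(p)]
    params: dict = {}
    if variant in ("aracne_a", "aracne_m"):
        thr = _dpi_threshold(mi)
        if variant == "aracne_a":
            keep = mi >= thr - eps
            params["eps"] = float(eps)
        else:
            keep = mi >= thr * (1.0 - tau)
            params["tau"] = float(tau)
        W = np.where(keep, mi, 0.0)
        W = np.minimum(W, W.T)
        np.fill_diagonal(W, 0.0)
    elif variant == "clr":
        W = _clr(mi)
    elif variant == "mrnet":
        S = np.vstack([_mrmr_scores(mi, t) for t in range(p)])  # S[t, j]
        W = np.maximum(S, S.T)
        np.fill_diagonal(W, 0.0)
    else:
        raise ValueError(f"unknown mutual-information variant {variant!r}")
    return WeightedNetwork(ids, W, signed=False, method=variant, params=params)


# ---------------------------------------------------------------------------
# unified dispatch


def default_grid(method: str) -> list[dict]:
    """Parameter grid explored per method when optimizing against a benchmark.

    Methods whose model selection is internal (correlation, simple/shrinkage
    partial correlation, and the cross-validated regression variants) have
    the single empty configuration.
    """
    if method == "glasso":
        return [{"rho": r} for r in GLASSO_RHOS]
    if method == "aracne_a":
        return [{"eps": e} for e in ARACNE_EPS]
    if method == "aracne_m":
        return [{"tau": t} for t in ARACNE_TAUS]
    if method in METHODS:
        return [{}]
    raise KeyError(f"unknown method {method!r}")


def fit_method(
    method: str,
    X,
    params: dict | None = None,
    seed: int = 0,
    mi_matrix: np.ndarray | None = None,
) -> WeightedNetwork:
    """Run one named estimator on a cohort matrix.

    ``mi_matrix`` lets the mutual-information family reuse one precomputed
    MI matrix across ARACNE/CLR/MRNET and across their parameter grids.
    """
    params = dict(params or {})
    if method == "pearsoncor":
        return infer_correlation(X, "pearson")
    if method == "spearmancor":
        return infer_correlation(X, "spearman")
    if method == "simpleparcor":
        return infer_parcor_inverse(X, "simple")
    if method == "genenet":
        return infer_parcor_inverse(X, "shrinkage")
    if method == "glasso":
        return infer_parcor_inverse(X, "glasso", rho=params.get("rho", 0.1))
    if method in ("ridgenet", "lassonet", "elasticnet", "plsnet"):
        variant = {"ridgenet": "ridge", "lassonet": "lasso", "elasticnet": "elasticnet", "plsnet": "pls"}[method]
        allowed = {"penalties", "l1_ratios", "max_components", "cv_folds"}
        kw = {k: v for k, v in params.items() if k in allowed}
        return infer_parcor_regression(X, variant, seed=seed, **kw)
    if method in MI_METHODS:
        if mi_matrix is None:
            mi_matrix = estimate_mi(X, k_neighbors=params.get("k_neighbors", DEFAULT_K_NEIGHBORS), seed=seed)
        _, ids = _as_matrix(X)
        kw = {k: params[k] for k in ("eps", "tau") if k in params}
        return infer_mi_network(mi_matrix, method, antibody_ids=ids, **kw)
    raise KeyError(f"unknown method {method!r}")
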