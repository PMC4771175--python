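"""Model/Results facade over the inference estimators.

``NetworkInference`` is constructed from data (a cohort matrix or an
:class:`~rppanet.data.ExpressionDataset` plus cohort name) and a method
name; ``fit()`` returns an :class:`InferredNetwork` results object carrying
the weighted network, the edge significance ranking, and a ``summary()``
table of the strongest edges.
"""

from __future__ import annotations

import pandas as pd

from .data import ExpressionDataset
from .inference import (
    METHODS,
    EdgeRanking,
    WeightedNetwork,
    estimate_mi,
    fit_method,
    rank_edges,
)

__all__ = ["NetworkInference", "InferredNetwork"]


class NetworkInference:
    """A network-inference model bound to one cohort matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Samples x antibodies expression matrix for one cohort.
    method : str
        One of the 13 estimator names in :data:`rppanet.inference.METHODS`.
    params : dict, optional
        Method parameters (e.g. ``rho`` for the graphical lasso, ``eps`` for
        additive-tolerance ARACNE, penalty grids for the regression family).
    seed : int
        Seed for all stochastic components (cross-validation folds, the MI
        estimator's tie-breaking noise).
    """

    def __init__(self, data: pd.DataFrame, method: str = "ridgenet", params: dict | None = None, seed: int = 0):
        if method not in METHODS:
            raise KeyError(f"unknown method {method!r}; choose from {METHODS}")
        self.data = data
        self.method = method
        self.params = dict(params or {})
        self.seed = seed

    @classmethod
    def from_dataset(cls, dataset: ExpressionDataset, cohort: str, **kwargs) -> "NetworkInference":
        return cls(dataset.cohort(cohort), **kwargs)

    def fit(self, mi_matrix=None) -> "InferredNetwork":
        net = fit_method(self.method, self.data, self.params, seed=self.seed, mi_matrix=mi_matrix)
        return InferredNetwork(model=self, network=net, ranking=rank_edges(net))

    def mi_matrix(self, k_neighbors: int = 3):
        """Precompute the pairwise MI matrix (for reuse across the MI family)."""
        return estimate_mi(self.data, k_neighbors=k_neighbors, seed=self.seed)


class InferredNetwork:
    """Fit results: the weighted network and its edge significance ranking."""

    def __init__(self, model: NetworkInference, network: WeightedNetwork, ranking: EdgeRanking):
        self.model = model
        self.network = network
        self.ranking = ranking

    @property
    def weights(self):
        return self.network.weights

    @property
    def antibody_ids(self):
        return self.network.antibody_ids

    def edge_table(self) -> pd.DataFrame:
        """All pairs with weight and tie-averaged significance rank."""
        w = self.network.edge_weights()
        r = self.ranking.rank_series()
        df = pd.DataFrame({"weight": w, "rank": r})
        df.index.names = ["antibody1", "antibody2"]
        return df.sort_values("rank")

    def summary(self, top: int = 10) -> str:
        n, p = self.model.data.shape
        head = self.edge_table().head(top)
        lines = [
            "Network inference results",
            "=" * 60,
            f"method:      {self.network.method}",
            f"samples:     {n}",
            f"antibodies:  {p}",
            f"signed:      {self.network.signed}",
            f"params:      {self.network.params}",
            "-" * 60,
            f"top {len(head)} edges by significance rank:",
            head.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)
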