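"""scikit-learn-style estimators wrapping the two weight predictors.

``NeighborSetRegressor`` treats edges as samples: ``fit(X, y)`` takes an
(n_edges, 2) array of node labels with their observed weights and builds
the training graph; ``predict(X)`` returns a weight for each queried node
pair.  This makes the predictor usable with sklearn model selection (an
edge train/test split is exactly the evaluation protocol's split).

``LinearCorrelationRegressor`` is the one-coefficient proportional
regression ŵ = λ·s on similarity scores.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from sklearn.base import BaseEstimator, RegressorMixin

from .baseline import LinearFit, fit_lambda, predict_linear
from .neighborset import NeighborSetPredictor

__all__ = ["NeighborSetRegressor", "LinearCorrelationRegressor"]


def _as_pairs(X) -> np.ndarray:
    X = np.asarray(X, dtype=object)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("X must be an (n, 2) array of node-label pairs")
    return X


class NeighborSetRegressor(RegressorMixin, BaseEstimator):
    """Predict edge weights of an undirected network from neighbor-set evidence.

    Parameters
    ----------
    normalize : bool, default=False
        Divide training weights by their maximum before fitting, so
        predictions are on the normalized (0, 1] scale.
    """

    def __init__(self, normalize: bool = False):
        self.normalize = normalize

    def fit(self, X, y):
        X = _as_pairs(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if np.any(~(y > 0)):
            raise ValueError("edge weights must be strictly positive")
        if self.normalize:
            y = y / y.max()
        G = nx.Graph()
        for (u, v), w in zip(X, y):
            if G.has_edge(u, v) and G[u][v]["weight"] != w:
                raise ValueError(f"conflicting duplicate edge ({u!r}, {v!r})")
            G.add_edge(u, v, weight=float(w))
        self.graph_ = G
        self.predictor_ = NeighborSetPredictor(G)
        self.n_features_in_ = 2
        return self

    @classmethod
    def from_graph(cls, G: nx.Graph, **params) -> "NeighborSetRegressor":
        """Fit directly from a weighted :class:`networkx.Graph`."""
        edges = [(u, v) for u, v in G.edges()]
        weights = [G[u][v]["weight"] for u, v in edges]
        return cls(**params).fit(np.array(edges, dtype=object), weights)

    def predict(self, X):
        if not hasattr(self, "predictor_"):
            raise ValueError("this NeighborSetRegressor instance is not fitted yet")
        X = _as_pairs(X)
        return np.array([self.predictor_.predict(u, v).predicted_weight for u, v in X])


class LinearCorrelationRegressor(RegressorMixin, BaseEstimator):
    """Proportional regression ŵ = λ·s with λ = (Σ sᵢwᵢ)/(Σ sᵢ²)."""

    def fit(self, X, y):
        s = np.asarray(X, dtype=float)
        if s.ndim == 2:
            if s.shape[1] != 1:
                raise ValueError("X must be a single score column")
            s = s.ravel()
        fit = fit_lambda(s, np.asarray(y, dtype=float).ravel())
        self.lambda_ = fit.lambda_
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "lambda_"):
            raise ValueError("this LinearCorrelationRegressor instance is not fitted yet")
        s = np.asarray(X, dtype=float)
        if s.ndim == 2:
            s = s.ravel()
        return predict_linear(s, LinearFit(self.lambda_))
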