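"""Random forest and epsilon-SVR, backed by scikit-learn."""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR

from ..errors import InvalidParameterError
from .base import FittedModel, RFParams, SVRParams, default_hyper, register


class _SkState:
    def __init__(self, estimator):
        self.estimator = estimator

    def _predict(self, X):
        return self.estimator.predict(X)


@register("rf")
def fit_rf(X, y, hyper: RFParams | None = None, seed: int = 0) -> FittedModel:
    """Bootstrap-aggregated regression trees; prediction = mean over trees."""
    hyper = hyper or default_hyper("rf")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0] or len(y) < 2:
        raise InvalidParameterError("X/y shapes invalid or n < 2")
    if hyper.n_trees < 1:
        raise InvalidParameterError("n_trees must be >= 1")
    est = RandomForestRegressor(
        n_estimators=hyper.n_trees,
        max_features=hyper.max_features,
        min_samples_leaf=hyper.min_samples_leaf,
        criterion="squared_error",  # variance-reduction splits
        random_state=seed,
        n_jobs=1,
    ).fit(X, y)
    return FittedModel(kind="rf", state=_SkState(est), n_features=X.shape[1],
                       hyper=hyper, seed=seed)


@register("svr")
def fit_svr(X, y, hyper: SVRParams | None = None, seed: int = 0) -> FittedModel:
    """epsilon-insensitive support vector regression with an RBF kernel."""
    hyper = hyper or default_hyper("svr")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0] or len(y) < 2:
        raise InvalidParameterError("X/y shapes invalid or n < 2")
    if hyper.penalty <= 0:
        raise InvalidParameterError("penalty weight must be > 0")
    if hyper.epsilon < 0:
        raise InvalidParameterError("epsilon must be >= 0")
    est = SVR(kernel="rbf", C=hyper.penalty, epsilon=hyper.epsilon,
              gamma=hyper.gamma, tol=1e-6).fit(X, y)
    return FittedModel(kind="svr", state=_SkState(est), n_features=X.shape[1],
                       hyper=hyper, seed=seed)
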