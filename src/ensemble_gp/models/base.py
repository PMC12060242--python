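"""Common fit/predict contract for the six predictors."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Callable, Dict, Optional

import numpy as np

from ..errors import InvalidParameterError, SchemaError

MODEL_KINDS = ("rrblup", "bayesb", "rkhs", "rf", "svr", "gat")


@dataclass
class FittedModel:
    """A trained predictor: kind tag, opaque learned state, training metadata.

    The state object exposes ``_predict(X) -> np.ndarray`` and, for the graph
    attention model, ``_input_gradient(X)``.
    """

    kind: str
    state: Any = field(repr=False)
    n_features: int
    hyper: Any = None
    seed: Optional[int] = None


def predict(model: FittedModel, X_new: np.ndarray) -> np.ndarray:
    """Predict one finite value per row; pure function of (state, X_new)."""
    X = np.asarray(X_new, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise SchemaError(
            f"X_new has {X.shape} columns; model was trained with "
            f"{model.n_features} features")
    out = np.asarray(model.state._predict(X), dtype=float).ravel()
    if len(out) != X.shape[0] or not np.all(np.isfinite(out)):
        raise SchemaError("prediction must return one finite value per row")
    return out


# ---------------------------------------------------------------------------
# hyperparameters (full-scale defaults; tests use scaled-down ones)
# ---------------------------------------------------------------------------

@dataclass
class RRBlupParams:
    method: str = "reml"          # "reml" | "mcmc" | "fixed"
    lambda_: Optional[float] = None  # required for method="fixed"
    n_iter: int = 12_000
    burn_in: int = 2_000
    fixed_cols: tuple = ()        # feature columns treated as fixed effects


@dataclass
class BayesBParams:
    n_iter: int = 12_000
    burn_in: int = 2_000
    pi0: float = 0.5              # prior mean inclusion probability
    pi_counts: float = 10.0       # Beta prior pseudo-counts for pi
    df_effect: float = 5.0        # slab scaled-inv-chi2 df
    df_resid: float = 5.0
    r2: float = 0.5               # assumed genic variance share, sets slab scale
    fixed_cols: tuple = ()


@dataclass
class RKHSParams:
    bandwidth: Optional[float] = None   # None -> median heuristic
    fixed_cols: tuple = ()


@dataclass
class RFParams:
    n_trees: int = 1_000
    max_features: float = 1 / 3
    min_samples_leaf: int = 1


@dataclass
class SVRParams:
    penalty: float = 1.0          # objective multiplier on the slack sum
    epsilon: float = 0.1          # insensitivity tube half-width
    gamma: Any = "scale"          # RBF width (sklearn semantics)


@dataclass
class GATParams:
    hidden_channels: int = 20
    n_layers: int = 3
    heads: int = 1
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 0.005
    weight_decay: float = 0.0
    dropout: float = 0.0
    negative_slope: float = 0.01


_DEFAULTS = {
    "rrblup": RRBlupParams,
    "bayesb": BayesBParams,
    "rkhs": RKHSParams,
    "rf": RFParams,
    "svr": SVRParams,
    "gat": GATParams,
}


def default_hyper(kind: str):
    if kind not in _DEFAULTS:
        raise InvalidParameterError(f"unknown model kind {kind!r}")
    return _DEFAULTS[kind]()


def test_profile_hyper(kind: str):
    """Scaled-down settings for CI-sized runs (documented in the README)."""
    hyper = default_hyper(kind)
    if kind in ("rrblup", "bayesb"):
        hyper.n_iter, hyper.burn_in = 1_500, 500
    elif kind == "rf":
        hyper.n_trees = 100
    elif kind == "gat":
        hyper.epochs = 20
    return hyper


def hyper_to_dict(hyper) -> Dict[str, Any]:
    return asdict(hyper) if hyper is not None else {}


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

MODEL_REGISTRY: Dict[str, Callable] = {}


def register(kind: str):
    def deco(fn):
        MODEL_REGISTRY[kind] = fn
        return fn
    return deco


def get_fitter(kind: str) -> Callable:
    if kind not in MODEL_REGISTRY:
        raise InvalidParameterError(f"unknown model kind {kind!r}")
    return MODEL_REGISTRY[kind]


# ---------------------------------------------------------------------------
# stub predictors (bookkeeping runs and tests)
# ---------------------------------------------------------------------------

class _StubState:
    def __init__(self, mean, slope, col):
        self.mean, self.slope, self.col = mean, slope, col

    def _predict(self, X):
        return self.mean + self.slope * (X[:, self.col] - 1.0)


def make_stub(name: str, slope: float = 0.0, col: int = 0) -> Callable:
    """A deterministic, trivially cheap fitter: train mean + slope*(x_col - 1).

    Distinct slopes give disagreeing stub models, so ensemble/decomposition
    bookkeeping can be exercised at full replication scale in seconds.
    """

    def fit_stub(X, y, hyper=None, seed=0):
        X = np.asarray(X, dtype=float)
        return FittedModel(kind=name, state=_StubState(float(np.mean(y)), slope, col),
                           n_features=X.shape[1], hyper=None, seed=seed)

    return fit_stub
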