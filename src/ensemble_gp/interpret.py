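"""Per-model marker-effect estimation and cross-model comparison.

Linear models expose their coefficients directly; kernel and support-vector
models are attributed by Monte-Carlo Shapley sampling; the forest by summed
impurity (variance) reduction; the attention network by integrated gradients.
Element-wise attributions are averaged over the test records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, InvalidParameterError, SchemaError
from .models.base import FittedModel
from .ensemble import PredictionMatrix


@dataclass(frozen=True)
class MarkerEffectTable:
    """One row per (model, marker): signed effect or non-negative importance."""

    df: pd.DataFrame = field(repr=False)
    n_test: int = 0

    _COLUMNS = ("model_kind", "marker_id", "effect")

    def __post_init__(self):
        for col in self._COLUMNS:
            if col not in self.df.columns:
                raise SchemaError(f"effect table missing column {col!r}")
        if self.df.duplicated(subset=["model_kind", "marker_id"]).any():
            raise SchemaError("duplicate (model, marker) row")
        object.__setattr__(self, "df", self.df.reset_index(drop=True))

    def effects(self) -> np.ndarray:
        return self.df["effect"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)


def _marker_columns(n_features: int, feature_names: Optional[Sequence[str]],
                    exclude: Sequence[int] = ()) -> tuple:
    """(column indices, marker ids) excluding fixed/environment columns."""
    if feature_names is not None and len(feature_names) != n_features:
        raise SchemaError("feature_names length mismatch")
    cols = []
    names = []
    for j in range(n_features):
        name = feature_names[j] if feature_names is not None else f"m{j}"
        if j in exclude or name == "env":
            continue
        cols.append(j)
        names.append(name)
    return tuple(cols), tuple(names)


def effects_from_coefficients(model: FittedModel,
                              feature_names: Optional[Sequence[str]] = None
                              ) -> MarkerEffectTable:
    """Allele-substitution effects: the fitted per-marker coefficients."""
    if model.kind not in ("rrblup", "bayesb"):
        raise ContractError(f"coefficient effects undefined for {model.kind!r}")
    state = model.state
    full = state.full_effects(model.n_features)
    cols, names = _marker_columns(model.n_features, feature_names,
                                  exclude=state.fixed_cols)
    df = pd.DataFrame({"model_kind": model.kind, "marker_id": list(names),
                       "effect": full[list(cols)]})
    return MarkerEffectTable(df=df)


def shapley_effects(predict_fn: Callable, X_test: np.ndarray,
                    background: np.ndarray, n_samples: int = 64,
                    seed: int = 0, model_kind: str = "model",
                    feature_names: Optional[Sequence[str]] = None,
                    return_se: bool = False):
    """Monte-Carlo permutation estimate of per-feature Shapley values.

    For each test row and each sampled permutation, a random background row
    supplies the "absent" feature values and features are switched to the test
    row's values in permutation order; the change in prediction at each switch
    is that feature's marginal contribution. Averaging over permutations
    estimates the subset-weighted marginal-contribution sum, and the final
    table averages over test rows.
    """
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if X_test.shape[0] == 0:
        raise InvalidParameterError("empty test set")
    if background.shape[0] == 0:
        raise InvalidParameterError("empty background set")
    if n_samples < 1:
        raise InvalidParameterError("n_samples must be >= 1")
    if background.shape[1] != X_test.shape[1]:
        raise SchemaError("background/test column mismatch")
    rng = np.random.default_rng(seed)
    n_test, p = X_test.shape
    # per (test row, sample, feature) marginal contributions
    contrib = np.zeros((n_test, n_samples, p))
    for r in range(n_test):
        x = X_test[r]
        for s in range(n_samples):
            perm = rng.permutation(p)
            z = background[rng.integers(background.shape[0])]
            # p+1 vectors: background, then switching one feature at a time
            V = np.tile(z, (p + 1, 1))
            for step, j in enumerate(perm, start=1):
                V[step:, j] = x[j]
            preds = np.asarray(predict_fn(V), dtype=float).ravel()
            contrib[r, s, perm] = np.diff(preds)
    phi_per_row = contrib.mean(axis=1)             # (n_test, p)
    phi = phi_per_row.mean(axis=0)
    cols, names = _marker_columns(p, feature_names)
    df = pd.DataFrame({"model_kind": model_kind, "marker_id": list(names),
                       "effect": phi[list(cols)]})
    table = MarkerEffectTable(df=df, n_test=n_test)
    if return_se:
        # MC error of the mean over (test row, permutation) draws
        flat = contrib.reshape(n_test * n_samples, p)
        se = flat.std(axis=0, ddof=1) / np.sqrt(flat.shape[0])
        return table, se[list(cols)]
    return table


def impurity_importance(model: FittedModel,
                        feature_names: Optional[Sequence[str]] = None
                        ) -> MarkerEffectTable:
    """Summed, tree-averaged variance reduction per feature (sums to 1)."""
    if model.kind != "rf":
        raise ContractError(f"impurity importance undefined for {model.kind!r}")
    imp = np.asarray(model.state.estimator.feature_importances_, dtype=float)
    cols, names = _marker_columns(model.n_features, feature_names)
    df = pd.DataFrame({"model_kind": "rf", "marker_id": list(names),
                       "effect": imp[list(cols)]})
    return MarkerEffectTable(df=df)


def integrated_gradients(model, X_test: np.ndarray,
                         baseline: Optional[np.ndarray] = None,
                         m_steps: int = 128,
                         feature_names: Optional[Sequence[str]] = None,
                         model_kind: str = "gat") -> MarkerEffectTable:
    """Riemann-sum path integral of prediction gradients from the baseline.

    IG_i(x) = (x_i - x'_i) * (1/m) * sum_{k=1..m} dF/dx_i at x' + (k/m)(x-x').
    ``model`` must expose ``_input_gradient`` (the attention network state
    does) or be an object with an ``input_gradient`` callable. Averaged over
    test rows; the default baseline is the all-zero dosage vector.
    """
    if m_steps < 1:
        raise InvalidParameterError("m_steps must be >= 1")
    grad_fn = _resolve_gradient_fn(model)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    p = X_test.shape[1]
    if baseline is None:
        baseline = np.zeros(p)
    baseline = np.asarray(baseline, dtype=float).ravel()
    if len(baseline) != p:
        raise SchemaError("baseline shape mismatch")
    diff = X_test - baseline[None, :]
    total = np.zeros_like(X_test)
    for k in range(1, m_steps + 1):
        pts = baseline[None, :] + (k / m_steps) * diff
        total += np.asarray(grad_fn(pts), dtype=float)
    ig = diff * total / m_steps                    # (n_test, p)
    cols, names = _marker_columns(p, feature_names)
    df = pd.DataFrame({"model_kind": model_kind, "marker_id": list(names),
                       "effect": ig.mean(axis=0)[list(cols)]})
    return MarkerEffectTable(df=df, n_test=X_test.shape[0])


def _resolve_gradient_fn(model):
    if isinstance(model, FittedModel):
        state = model.state
        if not hasattr(state, "_input_gradient"):
            raise ContractError(
                f"model kind {model.kind!r} does not expose input gradients")
        return state._input_gradient
    if hasattr(model, "input_gradient"):
        return model.input_gradient
    if callable(model):
        return model
    raise ContractError("no gradient function available on the given model")


@dataclass(frozen=True)
class AssociationReport:
    """Pairwise Pearson correlations of predictions and marker effects."""

    prediction_corr: pd.DataFrame = field(repr=False)
    effect_corr: pd.DataFrame = field(repr=False)
    effects_long: pd.DataFrame = field(repr=False)


def pairwise_associations(prediction_matrices: Sequence[PredictionMatrix],
                          effect_tables: Sequence[MarkerEffectTable],
                          qtl_marker_ids: Sequence[str] = ()
                          ) -> AssociationReport:
    """Model-by-model correlation of (a) pooled predictions, (b) pooled
    per-marker effects across scenarios, with QTL/non-QTL labels attached."""
    if not prediction_matrices:
        raise InvalidParameterError("need at least one prediction matrix")
    kinds = prediction_matrices[0].model_kinds
    if len(kinds) < 2:
        raise InvalidParameterError("need at least 2 models")
    for pm in prediction_matrices:
        if pm.model_kinds != kinds:
            raise SchemaError("prediction matrices have inconsistent models")
    pooled = np.vstack([pm.predictions for pm in prediction_matrices])
    pred_corr = pd.DataFrame(np.corrcoef(pooled.T), index=kinds, columns=kinds)

    frames = []
    scenario_counter: dict = {}
    for tab in effect_tables:
        d = tab.df.copy()
        for mk in d["model_kind"].unique():
            scen = scenario_counter.get(mk, 0)
            scenario_counter[mk] = scen + 1
            d.loc[d["model_kind"] == mk, "scenario"] = scen
        frames.append(d)
    long = pd.concat(frames, ignore_index=True)
    qtl = set(qtl_marker_ids)
    long["qtl_flag"] = long["marker_id"].isin(qtl)
    wide = long.pivot_table(index=["scenario", "marker_id"],
                            columns="model_kind", values="effect")
    wide = wide.dropna()
    if len(wide) < 2:
        raise SchemaError("not enough shared (scenario, marker) effect rows")
    effect_kinds = list(wide.columns)
    eff_corr = pd.DataFrame(np.corrcoef(wide.to_numpy().T),
                            index=effect_kinds, columns=effect_kinds)
    return AssociationReport(prediction_corr=pred_corr, effect_corr=eff_corr,
                             effects_long=long)
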