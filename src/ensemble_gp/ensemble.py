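"""Equal-weight model averaging and the error/diversity decomposition.

The squared error of the average prediction equals the average squared error
of the individual models minus the variance of their predictions around the
average ("the many-model error equals the average error minus the prediction
diversity"). Terms are reported on the MSE scale — each per-record term is
averaged over test records, which preserves the identity by linearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, SchemaError


@dataclass(frozen=True)
class PredictionMatrix:
    """Observed values plus one prediction column per model."""

    observed: np.ndarray
    predictions: np.ndarray        # (n_records, n_models)
    model_kinds: tuple

    def __post_init__(self):
        V = np.asarray(self.observed, dtype=float)
        M = np.asarray(self.predictions, dtype=float)
        if M.ndim != 2 or len(V) != M.shape[0]:
            raise SchemaError("predictions must be (n_records, n_models)")
        if M.shape[1] != len(self.model_kinds):
            raise SchemaError("model_kinds length must match prediction columns")
        if not (np.all(np.isfinite(V)) and np.all(np.isfinite(M))):
            raise SchemaError("prediction matrix contains non-finite values")
        object.__setattr__(self, "observed", V)
        object.__setattr__(self, "predictions", M)
        object.__setattr__(self, "model_kinds", tuple(self.model_kinds))

    @property
    def n_models(self) -> int:
        return self.predictions.shape[1]

    @property
    def n_records(self) -> int:
        return self.predictions.shape[0]


@dataclass(frozen=True)
class DPTDecomposition:
    """MSE-scale terms: ensemble_error = average_error - diversity."""

    ensemble_error: float
    average_error: float
    diversity: float
    n_models: int
    n_records: int

    def __post_init__(self):
        gap = abs(self.ensemble_error - (self.average_error - self.diversity))
        scale = max(abs(self.average_error), abs(self.diversity), 1.0)
        if gap > 1e-9 * scale:
            raise InvalidParameterError("decomposition identity violated")
        if self.diversity < -1e-12:
            raise InvalidParameterError("diversity must be non-negative")


def ensemble_average(pm: PredictionMatrix,
                     weights: Optional[Sequence[float]] = None) -> np.ndarray:
    """Per-record average of the model columns (uniform weights by default)."""
    if pm.n_models < 1 or pm.n_records < 1:
        raise InvalidParameterError("prediction matrix is empty")
    if weights is None:
        return pm.predictions.mean(axis=1)
    w = np.asarray(weights, dtype=float)
    if len(w) != pm.n_models:
        raise SchemaError("weights length must equal number of models")
    if abs(w.sum()) < 1e-12:
        raise InvalidParameterError("weights must not sum to zero")
    return pm.predictions @ (w / w.sum())


def dpt_first_term(average_error: float, diversity: float) -> float:
    """Ensemble (many-model) error implied by the identity: second - third."""
    return average_error - diversity


def dpt_decompose(pm: PredictionMatrix) -> DPTDecomposition:
    """Decompose squared error into ensemble error, average error, diversity."""
    if pm.n_models < 2:
        raise InvalidParameterError("decomposition needs at least 2 models")
    M = pm.predictions
    V = pm.observed
    Mbar = M.mean(axis=1)
    ens = float(np.mean((Mbar - V) ** 2))
    avg = float(np.mean(np.mean((M - V[:, None]) ** 2, axis=1)))
    div = float(np.mean(np.mean((M - Mbar[:, None]) ** 2, axis=1)))
    return DPTDecomposition(ensemble_error=ens, average_error=avg,
                            diversity=div, n_models=pm.n_models,
                            n_records=pm.n_records)


@dataclass(frozen=True)
class DecompositionSummary:
    """Pooled mean and standard error (sd/sqrt(n)) per decomposition term."""

    mean: dict
    se: dict
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for term in ("ensemble_error", "average_error", "diversity"):
            rows.append({"term": term, "mean": self.mean[term],
                         "se": self.se[term], "n": self.n})
        return pd.DataFrame(rows)


def aggregate_decompositions(decomps: Sequence[DPTDecomposition]
                             ) -> DecompositionSummary:
    """Mean +/- standard error of each term across scenarios (pooled)."""
    if len(decomps) == 0:
        raise InvalidParameterError("no decompositions to aggregate")
    terms = {t: np.array([getattr(d, t) for d in decomps])
             for t in ("ensemble_error", "average_error", "diversity")}
    n = len(decomps)
    mean = {t: float(v.mean()) for t, v in terms.items()}
    se = {t: (float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0)
          for t, v in terms.items()}
    return DecompositionSummary(mean=mean, se=se, n=n)
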