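"""Full factorial experiment: populations x traits x ratios x replicates.

Each cell gets a stable seed derived from the master seed, a fresh random
train/test split, one fit per model, a prediction matrix, per-model and
ensemble metrics, and an error/diversity decomposition. Summaries mirror the
trait-level decomposition table and the best-model percentage table.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._seeds import stable_seed
from .ensemble import (DPTDecomposition, PredictionMatrix,
                       aggregate_decompositions, dpt_decompose,
                       ensemble_average)
from .errors import InvalidParameterError, SchemaError, UndefinedMetricError
from .models.base import (MODEL_KINDS, default_hyper, get_fitter,
                          predict as model_predict, test_profile_hyper)
from .preprocess import FeatureTable, SplitSpec, split_train_test

logger = logging.getLogger(__name__)

ModelSpec = Union[str, Tuple[str, Callable]]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    """Product-moment correlation; undefined for constant vectors."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise SchemaError("pred/obs length mismatch")
    if len(pred) < 2:
        raise InvalidParameterError("pearson needs >= 2 records")
    if np.std(pred) == 0.0 or np.std(obs) == 0.0:
        raise UndefinedMetricError("pearson undefined for a constant vector")
    return float(np.corrcoef(pred, obs)[0, 1])


def mse(pred: np.ndarray, obs: np.ndarray) -> float:
    """Mean squared difference; 0 iff the vectors are identical."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise SchemaError("pred/obs length mismatch")
    if len(pred) == 0:
        raise InvalidParameterError("mse needs >= 1 record")
    return float(np.mean((pred - obs) ** 2))


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """Design of the evaluation grid.

    ``models`` entries are registered kind names or (name, fit_callable)
    pairs; ``profile`` chooses "test" (scaled-down CI settings) or "full"
    (the headline configuration: 12,000/2,000 MCMC, 1,000 trees, 50 epochs);
    ``hyper`` holds per-model overrides.
    """

    ratios: tuple = (0.8, 0.65, 0.5)
    replicates: int = 20
    models: tuple = MODEL_KINDS
    master_seed: int = 0
    profile: str = "test"
    hyper: Optional[Mapping[str, Any]] = None
    env_as_fixed_effect: bool = True

    def __post_init__(self):
        if not all(0.0 < r < 1.0 for r in self.ratios):
            raise InvalidParameterError("ratios must lie in (0, 1)")
        if self.replicates < 1:
            raise InvalidParameterError("replicates must be >= 1")
        if len(self.models) < 1:
            raise InvalidParameterError("need at least one model")
        if self.profile not in ("test", "full"):
            raise InvalidParameterError("profile must be 'test' or 'full'")


@dataclass(frozen=True)
class ExperimentResult:
    results: pd.DataFrame = field(repr=False)
    decompositions: pd.DataFrame = field(repr=False)
    failures: pd.DataFrame = field(repr=False)
    prediction_matrices: dict = field(repr=False, default_factory=dict)

    def dpt_summary(self) -> pd.DataFrame:
        """Trait-level mean +/- SE of each decomposition term (pooled)."""
        rows = []
        for trait, grp in self.decompositions.groupby("trait", sort=False):
            decs = [DPTDecomposition(r.ensemble_error, r.average_error,
                                     r.diversity, int(r.n_models),
                                     int(r.n_records))
                    for r in grp.itertuples(index=False)]
            summ = aggregate_decompositions(decs)
            row = {"trait": trait, "n_scenarios": summ.n}
            for term in ("ensemble_error", "average_error", "diversity"):
                row[f"{term}_mean"] = summ.mean[term]
                row[f"{term}_se"] = summ.se[term]
            rows.append(row)
        return pd.DataFrame(rows)


def _resolve_models(config: ExperimentConfig):
    resolved = []
    for spec in config.models:
        if isinstance(spec, str):
            resolved.append((spec, get_fitter(spec)))
        else:
            name, fn = spec
            resolved.append((name, fn))
    return resolved


def _hyper_for(name: str, config: ExperimentConfig, n_features: int):
    if config.hyper and name in config.hyper:
        hyper = config.hyper[name]
    else:
        try:
            hyper = (test_profile_hyper(name) if config.profile == "test"
                     else default_hyper(name))
        except InvalidParameterError:
            return None  # stub or custom callable without registered defaults
    if (config.env_as_fixed_effect and hasattr(hyper, "fixed_cols")
            and not hyper.fixed_cols):
        hyper = dataclasses.replace(hyper, fixed_cols=(n_features - 1,))
    return hyper


def run_experiment(datasets: Mapping[Tuple[str, str], FeatureTable],
                   config: ExperimentConfig,
                   keep_prediction_matrices: bool = False) -> ExperimentResult:
    """Run the full grid and collect metrics, decompositions, and failures.

    ``datasets`` maps (population, trait) to a model-ready feature table.
    Any model failure flags the whole scenario; it is excluded from results
    and summaries and logged with its cause.
    """
    models = _resolve_models(config)
    result_rows, dpt_rows, failure_rows = [], [], []
    pred_store = {}
    for (pop, trait), table in datasets.items():
        hypers = {name: _hyper_for(name, config, table.X.shape[1])
                  for name, _ in models}
        for ratio in config.ratios:
            for rep in range(config.replicates):
                cell_seed = stable_seed(config.master_seed, pop, trait,
                                        ratio, rep)
                spec = SplitSpec(train_fraction=ratio, replicate=rep,
                                 seed=cell_seed)
                train, test = split_train_test(table, spec)
                Xtr, ytr = table.X[train], table.y[train]
                Xte, yte = table.X[test], table.y[test]
                preds, kinds = [], []
                try:
                    for name, fit in models:
                        fitted = fit(Xtr, ytr, hypers[name],
                                     seed=stable_seed(cell_seed, name))
                        preds.append(model_predict(fitted, Xte))
                        kinds.append(name)
                except Exception as exc:  # noqa: BLE001 - flagged, not fatal
                    failure_rows.append({"population": pop, "trait": trait,
                                         "ratio": ratio, "replicate": rep,
                                         "model": name, "error": repr(exc)})
                    logger.warning("scenario (%s, %s, %s, %s) failed: %r",
                                   pop, trait, ratio, rep, exc)
                    continue
                pm = PredictionMatrix(observed=yte,
                                      predictions=np.column_stack(preds),
                                      model_kinds=tuple(kinds))
                if keep_prediction_matrices:
                    pred_store[(pop, trait, ratio, rep)] = pm
                ens = ensemble_average(pm)
                for name, vec in list(zip(kinds, preds)) + [("ensemble", ens)]:
                    row = {"population": pop, "trait": trait, "ratio": ratio,
                           "replicate": rep, "model": name,
                           "mse": mse(vec, yte)}
                    try:
                        row["pearson"] = pearson(vec, yte)
                    except UndefinedMetricError as exc:
                        row["pearson"] = np.nan
                        failure_rows.append(
                            {"population": pop, "trait": trait, "ratio": ratio,
                             "replicate": rep, "model": name,
                             "error": f"undefined metric: {exc}"})
                    result_rows.append(row)
                if pm.n_models >= 2:
                    dec = dpt_decompose(pm)
                    dpt_rows.append({"population": pop, "trait": trait,
                                     "ratio": ratio, "replicate": rep,
                                     "ensemble_error": dec.ensemble_error,
                                     "average_error": dec.average_error,
                                     "diversity": dec.diversity,
                                     "n_models": dec.n_models,
                                     "n_records": dec.n_records})
    results = pd.DataFrame(result_rows, columns=[
        "population", "trait", "ratio", "replicate", "model", "mse", "pearson"])
    decomps = pd.DataFrame(dpt_rows, columns=[
        "population", "trait", "ratio", "replicate", "ensemble_error",
        "average_error", "diversity", "n_models", "n_records"])
    failures = pd.DataFrame(failure_rows, columns=[
        "population", "trait", "ratio", "replicate", "model", "error"])
    return ExperimentResult(results=results, decompositions=decomps,
                            failures=failures,
                            prediction_matrices=pred_store)


def best_model_percentages(results: pd.DataFrame,
                           metrics: Sequence[str] = ("pearson", "mse")
                           ) -> pd.DataFrame:
    """Share of scenarios each model wins, per (ratio, trait, metric).

    The winner has the highest correlation / lowest error in a scenario
    (population x replicate); exact ties credit every tied model, so a row
    may exceed 100%.
    """
    if len(results) == 0:
        raise InvalidParameterError("empty result table")
    model_names = list(dict.fromkeys(results["model"]))
    rows = []
    for (ratio, trait), grp in results.groupby(["ratio", "trait"], sort=False):
        for metric in metrics:
            wins = {m: 0 for m in model_names}
            n_scen = 0
            for _, scen in grp.groupby(["population", "replicate"], sort=False):
                vals = scen.set_index("model")[metric].dropna()
                if len(vals) == 0:
                    continue
                n_scen += 1
                best = vals.max() if metric == "pearson" else vals.min()
                for m in vals.index[np.isclose(vals.to_numpy(), best)]:
                    wins[m] += 1
            for m in model_names:
                rows.append({"ratio": ratio, "trait": trait, "metric": metric,
                             "model": m,
                             "percentage": 100.0 * wins[m] / max(n_scen, 1)})
    return pd.DataFrame(rows)
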