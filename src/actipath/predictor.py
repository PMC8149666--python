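"""Step 1 — the prediction model behind a model-agnostic contract.

Any object exposing ``task`` and ``predict_frame`` can drive the
surrogate and the planner; the default engine is gradient-boosted trees
(XGBoost) with hyperparameters chosen by fivefold cross-validation over a
small grid. Discrete explanatory variables are one-hot encoded here, so
the surrogate downstream sees raw category labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Mapping, Optional, Protocol, runtime_checkable

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, KFold

from .dataset import Dataset
from .schema import VariableSchema

Task = Literal["regression", "classification"]

#: default cross-validated hyperparameter grid for the gradient-boosted engine
DEFAULT_GRID: dict = {
    "n_estimators": [100, 300],
    "max_depth": [2, 4],
    "learning_rate": [0.05, 0.1],
}


def encode_features(data: Dataset) -> pd.DataFrame:
    """Numeric design matrix: continuous columns as-is, discrete one-hot.

    One-hot columns are emitted for every schema category (not just the
    observed ones), so train/test/node encodings always align.
    """
    schema = data.schema
    out = data.x_continuous().astype(float).copy()
    for var in schema.discrete_explanatory:
        col = data.values[var.name]
        for cat in var.categories:
            out[f"{var.name}={cat}"] = (col == cat).astype(float)
    return out


def encode_row(row: Mapping[str, object], schema: VariableSchema) -> np.ndarray:
    vals = [float(row[v.name]) for v in schema.continuous_explanatory]
    for var in schema.discrete_explanatory:
        vals.extend(float(row[var.name] == cat) for cat in var.categories)
    return np.asarray(vals, dtype=float)


def response_as_numeric(data: Dataset) -> np.ndarray:
    """Response column as float; binary labels map to 0/1 by category order."""
    resp = data.schema.response
    y = data.y
    if resp.kind == "discrete":
        if len(resp.categories) != 2:
            raise ValueError("classification requires a binary response")
        return (y == resp.categories[1]).to_numpy(dtype=float)
    return y.to_numpy(dtype=float)


@runtime_checkable
class Predictor(Protocol):
    """The model-agnostic contract every prediction model satisfies."""

    task: Task

    def predict_frame(self, values: pd.DataFrame) -> np.ndarray: ...


@dataclass
class PredictionModel:
    """A fitted model plus its evaluation bookkeeping.

    ``predict_frame`` maps a value table (schema columns) to one real
    prediction per row: the predicted response for regression, the
    positive-class probability for classification. ``rmse_test`` is
    filled by :func:`evaluate` and later fixes the surrogate's response
    noise scale.
    """

    task: Task
    schema: VariableSchema
    _predict: Callable[[pd.DataFrame], np.ndarray] = field(repr=False)
    engine: str = "custom"
    params: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    schema_fingerprint: str = ""
    _booster: object = field(default=None, repr=False)

    def __post_init__(self):
        if not self.schema_fingerprint:
            self.schema_fingerprint = self.schema.fingerprint()

    @property
    def rmse_test(self) -> Optional[float]:
        return self.metrics.get("rmse_test")

    def predict_frame(self, values: pd.DataFrame) -> np.ndarray:
        out = np.asarray(self._predict(values), dtype=float)
        if self.task == "classification":
            if out.size and (out.min() < -1e-9 or out.max() > 1 + 1e-9):
                raise ValueError("classification predictions must lie in [0, 1]")
            out = np.clip(out, 0.0, 1.0)
        return out

    def predict_row(self, row: Mapping[str, object]) -> float:
        frame = pd.DataFrame([row])
        return float(self.predict_frame(frame)[0])

    # ------------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "engine": self.engine,
            "task": self.task,
            "params": self.params,
            "metrics": self.metrics,
            "schema": self.schema.to_dict(),
            "schema_fingerprint": self.schema_fingerprint,
        }
        if self.engine == "xgboost":
            booster_path = path.with_suffix(".ubj.json")
            booster = (
                self._booster.get_booster()
                if hasattr(self._booster, "get_booster")
                else self._booster
            )
            booster.save_model(str(booster_path))
            meta["booster_file"] = booster_path.name
        else:
            raise ValueError(f"engine {self.engine!r} does not support persistence")
        path.write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PredictionModel":
        import xgboost as xgb

        path = Path(path)
        meta = json.loads(path.read_text())
        if meta["engine"] != "xgboost":
            raise ValueError("only the xgboost engine is persistable")
        schema = VariableSchema.from_dict(meta["schema"])
        booster = xgb.Booster()
        booster.load_model(str(path.parent / meta["booster_file"]))
        return _wrap_booster(
            booster, meta["task"], schema, meta["params"], metrics=meta["metrics"]
        )


def function_predictor(
    fn: Callable[[pd.DataFrame], np.ndarray],
    schema: VariableSchema,
    task: Task = "regression",
    rmse_test: Optional[float] = None,
) -> PredictionModel:
    """Wrap a closed-form function as a predictor (the model-agnostic stub)."""
    metrics = {} if rmse_test is None else {"rmse_test": float(rmse_test)}
    return PredictionModel(
        task=task, schema=schema, _predict=fn, engine="function", metrics=metrics
    )


def _wrap_xgb(est, task, schema, params, metrics=None) -> PredictionModel:
    def _predict(values: pd.DataFrame) -> np.ndarray:
        data = Dataset(values, schema)
        X = encode_features(data).to_numpy()
        if task == "regression":
            return est.predict(X)
        return est.predict_proba(X)[:, 1]

    return PredictionModel(
        task=task,
        schema=schema,
        _predict=_predict,
        engine="xgboost",
        params=dict(params),
        metrics=dict(metrics or {}),
        _booster=est,
    )


def _wrap_booster(booster, task, schema, params, metrics=None) -> PredictionModel:
    """Predictor around a bare Booster (the persisted form)."""
    import xgboost as xgb

    def _predict(values: pd.DataFrame) -> np.ndarray:
        data = Dataset(values, schema)
        X = encode_features(data).to_numpy()
        out = booster.predict(xgb.DMatrix(X))
        return out  # binary:logistic already emits probabilities

    return PredictionModel(
        task=task,
        schema=schema,
        _predict=_predict,
        engine="xgboost",
        params=dict(params),
        metrics=dict(metrics or {}),
        _booster=booster,
    )


def fit_predictor(
    train: Dataset,
    task: Task = "regression",
    config: Optional[Mapping] = None,
) -> PredictionModel:
    """Fit the default gradient-boosted model with fivefold CV.

    ``config`` keys: ``grid`` (replaces :data:`DEFAULT_GRID`), ``params``
    (fixed hyperparameters, skips the search), ``seed``. Cross-validation
    scores by RMSE (regression) / AUC (classification).
    """
    import xgboost as xgb

    config = dict(config or {})
    if len(train) < 20:
        raise ValueError("need >= 20 training rows")
    if train.has_missing():
        raise ValueError("training data contains missing cells; impute first")
    y = response_as_numeric(train)
    if np.unique(y).size < 2:
        raise ValueError("degenerate response: constant value / single class")
    X = encode_features(train).to_numpy()
    seed = int(config.get("seed", 0))
    base_kwargs = dict(random_state=seed, n_jobs=1, verbosity=0)
    if task == "regression":
        est_cls, scoring = xgb.XGBRegressor, "neg_root_mean_squared_error"
    else:
        est_cls, scoring = xgb.XGBClassifier, "roc_auc"
        base_kwargs["eval_metric"] = "logloss"

    if "params" in config:
        params = dict(config["params"])
        est = est_cls(**base_kwargs, **params)
        est.fit(X, y)
    else:
        grid = config.get("grid", DEFAULT_GRID)
        search = GridSearchCV(
            est_cls(**base_kwargs),
            param_grid=grid,
            scoring=scoring,
            cv=KFold(5, shuffle=True, random_state=seed),
            n_jobs=1,
            refit=True,
        )
        search.fit(X, y)
        est, params = search.best_estimator_, dict(search.best_params_)
    return _wrap_xgb(est, task, train.schema, params)


def evaluate(model: PredictionModel, test: Dataset) -> dict:
    """Held-out metrics: RMSE + R^2 (regression) or AUC (classification).

    RMSE is stored on the model as ``rmse_test`` (it fixes the surrogate's
    response noise sd).
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    if test.has_missing():
        raise ValueError("test data contains missing cells; impute first")
    y = response_as_numeric(test)
    pred = model.predict_frame(test.values)
    if model.task == "regression":
        rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        r2 = float(r2_score(y, pred)) if np.unique(y).size > 1 else float("nan")
        model.metrics.update({"rmse_test": rmse, "r2": r2})
        return {"rmse_test": rmse, "r2": r2}
    if np.unique(y).size < 2:
        raise ValueError("single-class test set: AUC undefined")
    auc = float(roc_auc_score(y, pred))
    model.metrics.update({"auc": auc})
    return {"auc": auc}


def predict_table(model: PredictionModel, data: Dataset) -> np.ndarray:
    """One prediction per row; this vector is the surrogate's training response."""
    if list(data.values.columns) != model.schema.names:
        raise ValueError("data columns do not match the fitted schema")
    if len(data) == 0:
        return np.empty(0)
    return model.predict_frame(data.values)
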