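"""End-to-end orchestration of the three framework steps.

Glue used by the command-line driver, the test suite and the
reproduction script: preprocessing (impute -> standardize on training
statistics), prediction-model fitting and evaluation, and assembly of
the surrogate's training table (training rows only, 3-sigma filtered,
response = the prediction model's outputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .dataset import Dataset, Standardization
from .predictor import PredictionModel, evaluate, fit_predictor, predict_table
from .preprocess import (
    filter_outliers_3sigma,
    impute_median,
    split_train_test,
    standardize,
)
from .surrogate import SurrogateModel, fit_surrogate, select_k_by_wbic


@dataclass
class PreparedData:
    train: Dataset  # imputed + standardized
    test: Dataset
    train_raw: Dataset
    standardization: Standardization


def prepare_datasets(
    data: Dataset, train_fraction: float = 0.8, seed: int = 0
) -> PreparedData:
    """80/20 split, median/mode imputation and standardization.

    All statistics (medians, modes, means, sds) come from the training
    rows only and are applied to both sides of the split.
    """
    train_raw, test_raw = split_train_test(data, train_fraction, seed=seed)
    train_imp = impute_median(train_raw, train_raw)
    test_imp = impute_median(test_raw, train_raw)
    train_std = standardize(train_imp, train_imp)
    test_std = standardize(test_imp, train_imp)
    return PreparedData(
        train=train_std,
        test=test_std,
        train_raw=train_raw,
        standardization=train_std.standardization,
    )


def fit_step1(
    prepared: PreparedData,
    task: str = "regression",
    config: Optional[Mapping] = None,
) -> tuple[PredictionModel, dict]:
    model = fit_predictor(prepared.train, task=task, config=config)
    metrics = evaluate(model, prepared.test)
    return model, metrics


def surrogate_training_table(
    prepared: PreparedData, model: PredictionModel
) -> tuple[Dataset, np.ndarray]:
    """Training table for Step 2: 3-sigma filtered rows + predicted responses."""
    X, _report = filter_outliers_3sigma(prepared.train, prepared.train)
    y_pred = predict_table(model, X)
    return X, y_pred


def fit_step2(
    prepared: PreparedData,
    model: PredictionModel,
    k_range=range(1, 9),
    mcmc: Optional[Mapping] = None,
    fixed_k: Optional[int] = None,
) -> tuple[SurrogateModel, list[tuple[int, float]]]:
    """Select K by WBIC (unless fixed) and fit the surrogate at that K."""
    X, y_pred = surrogate_training_table(prepared, model)
    rmse = model.rmse_test
    if fixed_k is None:
        best_k, curve = select_k_by_wbic(
            X, y_pred, k_range=k_range, task=model.task, mcmc=mcmc, rmse_test=rmse
        )
    else:
        best_k, curve = int(fixed_k), []
    surrogate = fit_surrogate(
        X, y_pred, K=best_k, task=model.task, mcmc=mcmc, rmse_test=rmse
    )
    surrogate.wbic = dict(curve).get(best_k)
    return surrogate, curve
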