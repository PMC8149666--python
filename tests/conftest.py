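"""Shared fixtures: the 3D benchmark pipeline and hand-controlled stubs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import actipath as ap

# fixed, cheap hyperparameters for tests that are not about the CV search
FAST_XGB = {"params": {"n_estimators": 150, "max_depth": 3, "learning_rate": 0.1}}
SMALL_MCMC = {"iterations": 300, "warmup": 100, "chains": 2, "seed": 0}


@pytest.fixture(scope="session")
def bench_data():
    return ap.generate_synthetic3d(seed=1)


@pytest.fixture(scope="session")
def bench_prepared(bench_data):
    return ap.prepare_datasets(bench_data, train_fraction=0.8, seed=1)


@pytest.fixture(scope="session")
def bench_model(bench_prepared):
    model, _metrics = ap.fit_step1(bench_prepared, config={**FAST_XGB, "seed": 0})
    return model


@pytest.fixture(scope="session")
def bench_surrogate(bench_prepared, bench_model):
    X, y_pred = ap.surrogate_training_table(bench_prepared, bench_model)
    return ap.fit_surrogate(
        X, y_pred, K=2, mcmc=SMALL_MCMC, rmse_test=bench_model.rmse_test
    )


# ---------------------------------------------------------------------------
# hand-controlled lattice stubs (planner and scoring tests)
# ---------------------------------------------------------------------------


def lattice_schema(dim: int, directions=None) -> ap.VariableSchema:
    directions = directions or ["free"] * dim
    vars_ = [
        ap.Variable(f"x{i + 1}", intervenable=True, direction=directions[i])
        for i in range(dim)
    ]
    vars_.append(ap.Variable("y", role="response"))
    return ap.VariableSchema(vars_)


class LatticeDensity:
    """Surrogate stand-in with hand-assigned (synthetic) node log-probabilities.

    Built for unit grids with origin 0, so continuous coordinates round
    to the integer offsets keying ``table``. Satisfies the density
    contract the planner relies on without any MCMC.
    """

    def __init__(self, schema: ap.VariableSchema, table: dict, task="regression"):
        self.schema = schema
        self.table = table
        self.task = task

    def log_state_probability_batch(self, xc, codes, y, include_response=True):
        keys = [tuple(int(round(v)) for v in row) for row in np.asarray(xc)]
        return np.array([self.table[k] for k in keys], dtype=float)

    def log_state_probability(self, x, y=None, include_response=True):
        xc = [[float(x[v.name]) for v in self.schema.continuous_explanatory]]
        return float(
            self.log_state_probability_batch(xc, [], None, include_response)[0]
        )


def linear_predictor(schema: ap.VariableSchema, coefs: dict[str, float]):
    """Deterministic stub predictor: response = sum coef * value."""

    def fn(values: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(values))
        for name, c in coefs.items():
            out = out + c * values[name].to_numpy(dtype=float)
        return out

    return ap.function_predictor(fn, schema, task="regression", rmse_test=1.0)


def unit_grid(dim: int, lower: int, upper: int) -> ap.GridSpec:
    return ap.GridSpec(
        names=tuple(f"x{i + 1}" for i in range(dim)),
        steps=(1.0,) * dim,
        lower=(lower,) * dim,
        upper=(upper,) * dim,
        origin=(0.0,) * dim,
    )


def random_lattice_table(dim, lower, upper, seed) -> dict:
    rng = np.random.default_rng(seed)
    from itertools import product

    keys = list(product(range(lower, upper + 1), repeat=dim))
    return {k: float(rng.uniform(-4.0, -0.5)) for k in keys}


# ---------------------------------------------------------------------------
# small hand-built surrogate models (density tests)
# ---------------------------------------------------------------------------


def make_surrogate(
    pi, m, var, beta1=None, eta_cont=None, schema=None, sigma=1.0, phi=None,
    eta_disc=None, task="regression",
):
    """Assemble a SurrogateModel directly from parameter draws.

    Arrays follow the draw layout: pi (S, K), m/var (S, K, d), etc.
    Missing response-head parameters default to zero.
    """
    pi = np.asarray(pi, float)
    m = np.asarray(m, float)
    var = np.asarray(var, float)
    S, K, d = m.shape
    if schema is None:
        schema = lattice_schema(d)
    draws = {
        "pi": pi,
        "m": m,
        "var": var,
        "beta1": np.zeros((S, K)) if beta1 is None else np.asarray(beta1, float),
        "eta_cont": np.zeros((S, K, d))
        if eta_cont is None
        else np.asarray(eta_cont, float),
        "eta_disc": np.zeros((S, K, 0))
        if eta_disc is None
        else np.asarray(eta_disc, float),
        "phi": [] if phi is None else [np.asarray(p, float) for p in phi],
    }
    return ap.SurrogateModel(
        task=task, K=K, schema=schema, draws=draws, sigma=sigma
    )
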