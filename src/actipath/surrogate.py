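"""Step 2 — the stochastic surrogate: a hierarchical Bayesian mixture of experts.

The surrogate is a K-component mixture fitted to the training instances'
explanatory values together with the prediction model's outputs. Each
component owns a diagonal-covariance Gaussian over the continuous
variables, categorical tables over the discrete variables, and a linear
(regression) or logistic (classification) response head. The response
noise sd is fixed at half the prediction model's held-out RMSE, tying
the surrogate's tolerance to the predictor's accuracy. The component
label is marginalized in every density evaluation, and densities are
averaged over posterior draws in the log domain (posterior predictive).

Model choice over K uses the widely applicable Bayesian information
criterion (WBIC): the expected total negative log-likelihood under the
posterior tempered at inverse temperature 1/log n; lower is better.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np

from ._gibbs import MixtureData, MixtureSampler, split_rhat
from .dataset import Dataset
from .schema import VariableSchema

Task = Literal["regression", "classification"]

#: sampler settings matching the study defaults
DEFAULT_MCMC = {"iterations": 1500, "warmup": 500, "chains": 4, "seed": 0}


def _prepare_data(X: Dataset, y: np.ndarray, task: Task) -> MixtureData:
    if X.has_missing():
        raise ValueError("surrogate training data must have no missing cells")
    xc = X.x_continuous().to_numpy(dtype=float)
    disc_vars = X.schema.discrete_explanatory
    codes, n_cat, onehots = [], [], []
    for var in disc_vars:
        col = X.values[var.name]
        code = np.asarray(
            [var.categories.index(v) for v in col], dtype=int
        )
        codes.append(code)
        n_cat.append(len(var.categories))
        eye = np.eye(len(var.categories))
        onehots.append(eye[code])
    xd1h = np.hstack(onehots) if onehots else np.zeros((len(X), 0))
    y = np.asarray(y, dtype=float)
    if y.shape != (len(X),):
        raise ValueError("y_pred is not aligned with the rows of X")
    if task == "classification":
        y = (y >= 0.5).astype(float)
    return MixtureData(xc=xc, disc_codes=codes, n_categories=n_cat, xd1h=xd1h, y=y)


@dataclass
class SurrogateModel:
    """Posterior draws of all mixture parameters plus bookkeeping.

    ``draws`` arrays are stacked over chains: ``pi`` (S, K), ``m`` and
    ``var`` (S, K, d) — ``var`` holds the diagonal covariance entries —
    ``phi`` a list of (S, K, C_j) per discrete variable, ``beta1`` (S, K),
    ``eta_cont`` (S, K, d), ``eta_disc`` (S, K, p).
    """

    task: Task
    K: int
    schema: VariableSchema
    draws: dict
    sigma: Optional[float] = None  # fixed response noise sd = rmse_test / 2
    y_mean: float = 0.0
    y_std: float = 1.0
    wbic: Optional[float] = None
    mcmc: dict = field(default_factory=dict)
    temperature: float = 1.0
    convergence: dict = field(default_factory=dict)

    def __post_init__(self):
        pi = self.draws["pi"]
        if np.abs(pi.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("mixture-weight draws do not sum to 1")
        if (self.draws["var"] <= 0).any():
            raise ValueError("diagonal covariance draws must be positive")
        for phi in self.draws["phi"]:
            if np.abs(phi.sum(axis=2) - 1.0).max() > 1e-8:
                raise ValueError("category-probability draws do not sum to 1")
        if self.task == "regression" and (self.sigma is None or self.sigma <= 0):
            raise ValueError("regression surrogate requires sigma > 0")

    @property
    def n_draws(self) -> int:
        return self.draws["pi"].shape[0]

    # ----------------------------------------------------------------- density
    def _row_arrays(self, x: Mapping[str, object]) -> tuple[np.ndarray, list[int]]:
        xc = np.asarray(
            [float(x[v.name]) for v in self.schema.continuous_explanatory]
        )
        codes = [
            v.categories.index(x[v.name]) for v in self.schema.discrete_explanatory
        ]
        if not np.all(np.isfinite(xc)):
            raise ValueError("non-finite continuous value in state vector")
        return xc, codes

    def log_state_probability(
        self,
        x: Mapping[str, object],
        y: Optional[float] = None,
        include_response: bool = True,
    ) -> float:
        """Log posterior-predictive density of a full variable state.

        ``y`` is the prediction model's output at ``x`` (the predicted
        response for regression, the positive-class probability for
        classification; the latter is scored through a probability-
        weighted Bernoulli term, which reduces to the plain pmf for hard
        0/1 labels). With ``include_response=False`` only the explanatory
        state is scored.
        """
        xc, codes = self._row_arrays(x)
        codes = [np.array([c]) for c in codes]
        return float(
            self._log_density(xc[None, :], codes, None if y is None else np.array([y]),
                              include_response)[0]
        )

    def log_state_probability_batch(
        self,
        xc: np.ndarray,
        codes: Sequence[Sequence[int]] | None,
        y: Optional[np.ndarray],
        include_response: bool = True,
    ) -> np.ndarray:
        """Vectorized density over rows of ``xc`` (standardized units)."""
        codes = [np.asarray(c, dtype=int) for c in (codes or [])]
        return self._log_density(np.asarray(xc, float), codes, y, include_response)

    def _log_density(self, xc, codes, y, include_response) -> np.ndarray:
        if include_response and y is None:
            raise ValueError("y is required when the response term is included")
        n = xc.shape[0]
        pi = self.draws["pi"]  # (S, K)
        m = self.draws["m"]  # (S, K, d)
        var = self.draws["var"]
        S, K, d = m.shape
        # (n, S, K): continuous term
        diff = xc[:, None, None, :] - m[None, :, :, :]
        comp = -0.5 * np.sum(
            np.log(2.0 * np.pi * var)[None] + diff * diff / var[None], axis=3
        )
        comp = comp + np.log(np.clip(pi, 1e-300, None))[None]
        for j, code in enumerate(codes):
            phi = self.draws["phi"][j]  # (S, K, C)
            comp = comp + np.log(np.clip(phi[:, :, code], 1e-300, None)).transpose(
                2, 0, 1
            )
        if include_response:
            y = np.asarray(y, dtype=float)
            if not np.all(np.isfinite(y)):
                raise ValueError("non-finite response value")
            mu = self.draws["beta1"][None] + np.einsum(
                "nd,skd->nsk", xc, self.draws["eta_cont"]
            )
            if self.draws["eta_disc"].shape[2] and codes:
                x1h = _onehot_from_codes(codes, self.schema)
                mu = mu + np.einsum("np,skp->nsk", x1h, self.draws["eta_disc"])
            if self.task == "regression":
                z = (y[:, None, None] - mu) / self.sigma
                comp = comp + (
                    -0.5 * np.log(2.0 * np.pi * self.sigma**2) - 0.5 * z * z
                )
            else:
                from scipy.special import log_expit

                w = y[:, None, None]
                comp = comp + w * log_expit(mu) + (1.0 - w) * log_expit(-mu)
        # logsumexp over components, log-mean-exp over draws
        a = comp.max(axis=2, keepdims=True)
        per_draw = a[:, :, 0] + np.log(np.exp(comp - a).sum(axis=2))
        b = per_draw.max(axis=1, keepdims=True)
        out = b[:, 0] + np.log(np.exp(per_draw - b).mean(axis=1))
        return out

    # ------------------------------------------------------------------- misc
    def thin(self, max_draws: int, seed: int = 0) -> "SurrogateModel":
        """Evenly thin posterior draws (planning-time speedup)."""
        S = self.n_draws
        if S <= max_draws:
            return self
        idx = np.linspace(0, S - 1, max_draws).round().astype(int)
        draws = {
            "pi": self.draws["pi"][idx],
            "m": self.draws["m"][idx],
            "var": self.draws["var"][idx],
            "phi": [p[idx] for p in self.draws["phi"]],
            "beta1": self.draws["beta1"][idx],
            "eta_cont": self.draws["eta_cont"][idx],
            "eta_disc": self.draws["eta_disc"][idx],
        }
        return SurrogateModel(
            task=self.task,
            K=self.K,
            schema=self.schema,
            draws=draws,
            sigma=self.sigma,
            y_mean=self.y_mean,
            y_std=self.y_std,
            wbic=self.wbic,
            mcmc={**self.mcmc, "thinned_to": int(max_draws)},
            temperature=self.temperature,
            convergence=self.convergence,
        )

    # ------------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        """Columnar archive (npz) plus a JSON manifest next to it."""
        path = Path(path)
        arrays = {
            k: self.draws[k]
            for k in ("pi", "m", "var", "beta1", "eta_cont", "eta_disc")
        }
        for j, phi in enumerate(self.draws["phi"]):
            arrays[f"phi_{j}"] = phi
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        manifest = {
            "task": self.task,
            "K": self.K,
            "sigma": self.sigma,
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "wbic": self.wbic,
            "mcmc": self.mcmc,
            "temperature": self.temperature,
            "convergence": self.convergence,
            "n_phi": len(self.draws["phi"]),
            "schema": self.schema.to_dict(),
        }
        path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SurrogateModel":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".manifest.json").read_text())
        arch = np.load(path.with_suffix(".npz"))
        draws = {
            k: arch[k] for k in ("pi", "m", "var", "beta1", "eta_cont", "eta_disc")
        }
        draws["phi"] = [arch[f"phi_{j}"] for j in range(manifest["n_phi"])]
        return cls(
            task=manifest["task"],
            K=manifest["K"],
            schema=VariableSchema.from_dict(manifest["schema"]),
            draws=draws,
            sigma=manifest["sigma"],
            y_mean=manifest["y_mean"],
            y_std=manifest["y_std"],
            wbic=manifest["wbic"],
            mcmc=manifest["mcmc"],
            temperature=manifest["temperature"],
            convergence=manifest["convergence"],
        )


def _onehot_from_codes(codes, schema: VariableSchema) -> np.ndarray:
    blocks = []
    for var, code in zip(schema.discrete_explanatory, codes):
        eye = np.eye(len(var.categories))
        blocks.append(eye[np.asarray(code, int)])
    return np.hstack(blocks)


# --------------------------------------------------------------------- fitting
def fit_surrogate(
    X: Dataset,
    y_pred: np.ndarray,
    K: int,
    task: Task = "regression",
    mcmc: Optional[Mapping] = None,
    temperature: float = 1.0,
    rmse_test: Optional[float] = None,
) -> SurrogateModel:
    """Sample the surrogate posterior for a fixed component count K.

    ``X`` must already be standardized (continuous explanatory columns)
    and 3-sigma filtered; ``y_pred`` is the prediction model's output per
    row. For regression, ``rmse_test`` fixes the response noise sd at
    ``rmse_test / 2``. ``temperature`` is the likelihood inverse
    temperature (1 for the ordinary posterior).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    settings = {**DEFAULT_MCMC, **dict(mcmc or {})}
    if task == "regression":
        if rmse_test is None or rmse_test <= 0:
            raise ValueError("regression requires rmse_test > 0 (fit/evaluate first)")
        sigma = rmse_test / 2.0
    else:
        sigma = None
    data = _prepare_data(X, y_pred, task)
    chains = int(settings["chains"])
    seeds = np.random.SeedSequence(int(settings["seed"])).spawn(chains)
    chain_draws = []
    for c in range(chains):
        sampler = MixtureSampler(
            data, K=K, task=task, sigma=sigma, temperature=temperature
        )
        rng = np.random.default_rng(seeds[c])
        chain_draws.append(
            sampler.run(
                int(settings["iterations"]), int(settings["warmup"]), rng
            )
        )
    draws = {
        k: np.concatenate([cd[k] for cd in chain_draws], axis=0)
        for k in ("pi", "m", "var", "beta1", "eta_cont", "eta_disc", "loglik")
    }
    draws["phi"] = [
        np.concatenate([cd["phi"][j] for cd in chain_draws], axis=0)
        for j in range(len(data.n_categories))
    ]
    convergence = _convergence_report(chain_draws)
    first = MixtureSampler(data, K=K, task=task, sigma=sigma, temperature=temperature)
    return SurrogateModel(
        task=task,
        K=K,
        schema=X.schema,
        draws=draws,
        sigma=sigma,
        y_mean=first.y_mean,
        y_std=first.y_std,
        mcmc={**settings, "n_draws": draws["pi"].shape[0]},
        temperature=temperature,
        convergence=convergence,
    )


def _convergence_report(chain_draws: list[dict]) -> dict:
    """Split-chain scale reduction per scalar parameter.

    Mixture posteriors are invariant under component relabeling, so
    per-component R-hats can be inflated by label switching across
    chains; the label-invariant total log-likelihood R-hat is reported
    alongside the per-parameter maximum.
    """
    def stack(key):
        return np.stack([cd[key].reshape(cd[key].shape[0], -1) for cd in chain_draws])

    rhats = {}
    for key in ("pi", "m", "var", "beta1", "eta_cont", "eta_disc"):
        arr = stack(key)  # (chains, draws, q)
        if arr.shape[2] == 0:
            continue
        vals = [split_rhat(arr[:, :, q]) for q in range(arr.shape[2])]
        vals = [v for v in vals if np.isfinite(v)]
        if vals:
            rhats[key] = float(np.max(vals))
    ll = np.stack([cd["loglik"] for cd in chain_draws])
    out = {"rhat_max_per_block": rhats, "rhat_loglik": float(split_rhat(ll))}
    finite = [v for v in rhats.values() if np.isfinite(v)]
    out["rhat_max"] = float(np.max(finite)) if finite else float("nan")
    return out


def wbic(
    X: Dataset,
    y_pred: np.ndarray,
    K: int,
    task: Task = "regression",
    mcmc: Optional[Mapping] = None,
    rmse_test: Optional[float] = None,
) -> float:
    """WBIC for one component count.

    Samples the posterior tempered at inverse temperature 1/log n and
    returns the expectation of the total negative log-likelihood; lower
    is better.
    """
    n = len(X)
    if n < 3 or np.log(n) <= 1.0:
        raise ValueError("WBIC needs n >= 3 (log n > 1)")
    model = fit_surrogate(
        X,
        y_pred,
        K,
        task=task,
        mcmc=mcmc,
        temperature=1.0 / float(np.log(n)),
        rmse_test=rmse_test,
    )
    return float(-np.mean(model.draws["loglik"]))


def select_k_by_wbic(
    X: Dataset,
    y_pred: np.ndarray,
    k_range: Iterable[int] = range(1, 9),
    task: Task = "regression",
    mcmc: Optional[Mapping] = None,
    rmse_test: Optional[float] = None,
) -> tuple[int, list[tuple[int, float]]]:
    """Argmin-WBIC component count plus the full WBIC curve."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be nonempty")
    settings = {**DEFAULT_MCMC, **dict(mcmc or {})}
    curve = []
    for K in k_range:
        # independent, reproducible substream per K
        k_settings = {**settings, "seed": (int(settings["seed"]) * 1000 + K) % (2**31)}
        curve.append(
            (K, wbic(X, y_pred, K, task=task, mcmc=k_settings, rmse_test=rmse_test))
        )
    best = min(curve, key=lambda kv: kv[1])[0]
    return best, curve
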