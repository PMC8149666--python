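"""Self-contained MCMC backend for the mixture-of-experts surrogate.

Samples the posterior of the marginalized mixture (component labels
summed out) by univariate slice sampling within a Gibbs scan over all
scalar parameters, on unconstrained scales:

* mixture weights and category probabilities via the stick-breaking
  transform (with its log-Jacobian, so a Dirichlet(1) prior is uniform);
* per-component diagonal scales via log-sd;
* means, intercepts and regression coefficients directly.

Marginalizing the labels makes the same code exact at any likelihood
temperature, which is what the WBIC computation needs; slice sampling
keeps the sampler tuning-free. Per-scalar updates touch one mixture
component, so the log-likelihood is refreshed from cached per-component
terms in O(n) per proposal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import log_expit
from sklearn.cluster import KMeans

_LOG2PI = float(np.log(2.0 * np.pi))


# ------------------------------------------------------------------ transforms
def simplex_from_raw(raw: np.ndarray) -> tuple[np.ndarray, float]:
    """Stick-breaking: unconstrained (K-1,) -> K-simplex, with log-Jacobian."""
    K = raw.size + 1
    pi = np.empty(K)
    log_stick = 0.0
    logjac = 0.0
    for k in range(K - 1):
        adj = raw[k] - np.log(K - 1 - k)
        # z = logistic(adj), computed in log domain for stability
        log_z = log_expit(adj)
        log_1mz = log_expit(-adj)
        pi[k] = np.exp(log_stick + log_z)
        logjac += log_stick + log_z + log_1mz
        log_stick += log_1mz
    pi[K - 1] = np.exp(log_stick)
    return pi, logjac


def raw_from_simplex(pi: np.ndarray) -> np.ndarray:
    """Inverse stick-breaking (for initialization)."""
    pi = np.clip(np.asarray(pi, float), 1e-9, None)
    pi = pi / pi.sum()
    K = pi.size
    raw = np.empty(K - 1)
    stick = 1.0
    for k in range(K - 1):
        z = np.clip(pi[k] / stick, 1e-9, 1 - 1e-9)
        raw[k] = np.log(z / (1 - z)) + np.log(K - 1 - k)
        stick *= 1 - z
    return raw


# ---------------------------------------------------------------- slice sampler
def slice_sample_step(
    x0: float,
    logp,
    logp0: float,
    w: float,
    rng: np.random.Generator,
    max_steps: int = 20,
) -> tuple[float, float]:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    logy = logp0 - rng.exponential()
    u = rng.random()
    left = x0 - w * u
    right = left + w
    j = int(rng.integers(0, max_steps))
    k = max_steps - 1 - j
    lp_left = logp(left)
    while j > 0 and lp_left > logy:
        left -= w
        j -= 1
        lp_left = logp(left)
    lp_right = logp(right)
    while k > 0 and lp_right > logy:
        right += w
        k -= 1
        lp_right = logp(right)
    while True:
        x1 = left + rng.random() * (right - left)
        lp1 = logp(x1)
        if lp1 > logy:
            return x1, lp1
        if x1 < x0:
            left = x1
        else:
            right = x1
        if right - left < 1e-12:
            return x0, logp0


# ---------------------------------------------------------------------- model
@dataclass
class MixtureData:
    """Training arrays for the surrogate sampler."""

    xc: np.ndarray  # (n, d) standardized continuous explanatory values
    disc_codes: list[np.ndarray]  # per discrete variable, (n,) int codes
    n_categories: list[int]
    xd1h: np.ndarray  # (n, p) one-hot of the discrete variables
    y: np.ndarray  # (n,) predicted response (regression) or 0/1 labels

    @property
    def n(self) -> int:
        return self.xc.shape[0]

    @property
    def d(self) -> int:
        return self.xc.shape[1]

    @property
    def p(self) -> int:
        return self.xd1h.shape[1]


class _State:
    """Parameter state plus cached per-component log-likelihood terms."""

    def __init__(self, data: MixtureData, K: int, task: str, sigma: Optional[float],
                 y_mean: float, y_std: float):
        self.data = data
        self.K = K
        self.task = task
        self.sigma = sigma
        self.y_mean = y_mean
        self.y_std = y_std
        n, d, p = data.n, data.d, data.p
        self.alpha = np.zeros(max(K - 1, 0))
        self.m = np.zeros((K, d))
        self.log_s = np.zeros((K, d))
        self.phi_raw = [np.zeros((K, max(c - 1, 0))) for c in data.n_categories]
        self.beta1 = np.zeros(K)
        self.eta_c = np.zeros((K, d))
        self.eta_d = np.zeros((K, p))
        # caches
        self.log_pi = np.full(K, -np.log(K))
        self.cont3 = np.zeros((n, K, d))   # per-variable continuous log-density
        self.disc = np.zeros((n, K))       # categorical log-probability
        self.resp = np.zeros((n, K))       # response-head log-likelihood
        self.mu = np.zeros((n, K))
        self.log_phi = [np.zeros((K, c)) for c in data.n_categories]

    # ------------------------------------------------------------ cache refresh
    def refresh_all(self) -> None:
        pi, _ = simplex_from_raw(self.alpha) if self.K > 1 else (np.ones(1), 0.0)
        self.log_pi = np.log(np.clip(pi, 1e-300, None))
        for k in range(self.K):
            for j in range(self.data.d):
                self._refresh_cont(k, j)
            self._refresh_mu(k)
            self._refresh_resp(k)
        for j in range(len(self.data.disc_codes)):
            for k in range(self.K):
                self._refresh_phi(j, k)
        self._refresh_disc()

    def _refresh_cont(self, k: int, j: int) -> None:
        s = np.exp(self.log_s[k, j])
        z = (self.data.xc[:, j] - self.m[k, j]) / s
        self.cont3[:, k, j] = -0.5 * _LOG2PI - self.log_s[k, j] - 0.5 * z * z

    def _refresh_mu(self, k: int) -> None:
        self.mu[:, k] = (
            self.beta1[k]
            + self.data.xc @ self.eta_c[k]
            + (self.data.xd1h @ self.eta_d[k] if self.data.p else 0.0)
        )

    def _refresh_resp(self, k: int) -> None:
        if self.task == "regression":
            z = (self.data.y - self.mu[:, k]) / self.sigma
            self.resp[:, k] = -0.5 * _LOG2PI - np.log(self.sigma) - 0.5 * z * z
        else:
            mu = self.mu[:, k]
            self.resp[:, k] = np.where(
                self.data.y > 0.5, log_expit(mu), log_expit(-mu)
            )

    def _refresh_phi(self, j: int, k: int) -> None:
        c = self.data.n_categories[j]
        if c == 0:
            return
        phi, _ = simplex_from_raw(self.phi_raw[j][k]) if c > 1 else (np.ones(1), 0.0)
        self.log_phi[j][k] = np.log(np.clip(phi, 1e-300, None))

    def _refresh_disc(self) -> None:
        self.disc[:] = 0.0
        for j, codes in enumerate(self.data.disc_codes):
            for k in range(self.K):
                self.disc[:, k] += self.log_phi[j][k][codes]

    # ------------------------------------------------------------- likelihoods
    def component_matrix(self) -> np.ndarray:
        return self.log_pi[None, :] + self.cont3.sum(axis=2) + self.disc + self.resp

    def loglik(self) -> float:
        """Total (untempered) log-likelihood of the marginalized mixture."""
        M = self.component_matrix()
        a = M.max(axis=1)
        return float(np.sum(a + np.log(np.exp(M - a[:, None]).sum(axis=1))))

    def rest_of(self, k: int) -> np.ndarray:
        """Per-row logsumexp over all components except ``k``."""
        M = self.component_matrix()
        if self.K == 1:
            return np.full(self.data.n, -np.inf)
        M = np.delete(M, k, axis=1)
        a = M.max(axis=1)
        return a + np.log(np.exp(M - a[:, None]).sum(axis=1))

def _loglik_from_rest(rest: np.ndarray, col: np.ndarray) -> float:
    # logaddexp(-inf, col) = col, so the K = 1 case needs no special path
    return float(np.sum(np.logaddexp(rest, col)))


# ---------------------------------------------------------------- Gibbs sweep
class MixtureSampler:
    """Slice-within-Gibbs sampler for the mixture-of-experts surrogate."""

    def __init__(
        self,
        data: MixtureData,
        K: int,
        task: str = "regression",
        sigma: Optional[float] = None,
        temperature: float = 1.0,
    ):
        if K < 1:
            raise ValueError("K must be >= 1")
        if task == "regression" and (sigma is None or sigma <= 0):
            raise ValueError("regression requires a positive sigma")
        self.data = data
        self.K = K
        self.task = task
        self.temp = float(temperature)
        y = data.y
        self.y_mean = float(np.mean(y)) if task == "regression" else 0.0
        self.y_std = float(np.std(y)) if task == "regression" else 1.0
        self.sigma = sigma
        self.state = _State(data, K, task, sigma, self.y_mean, self.y_std)

    # ---------------------------------------------------------------- init
    def initialize(self, rng: np.random.Generator, jitter: float = 0.05) -> None:
        """K-means initialization with per-chain jitter."""
        data, K, st = self.data, self.K, self.state
        if K == 1:
            labels = np.zeros(data.n, dtype=int)
        else:
            km = KMeans(
                n_clusters=K, n_init=5, random_state=int(rng.integers(2**31))
            ).fit(data.xc)
            labels = km.labels_
        counts = np.bincount(labels, minlength=K).astype(float)
        if K > 1:
            st.alpha = raw_from_simplex((counts + 1.0) / (counts + 1.0).sum())
        for k in range(K):
            rows = labels == k
            if rows.sum() >= 2:
                st.m[k] = data.xc[rows].mean(axis=0)
                st.log_s[k] = np.log(np.clip(data.xc[rows].std(axis=0), 0.05, None))
                yk = data.y[rows]
            else:
                st.m[k] = data.xc.mean(axis=0)
                st.log_s[k] = np.log(np.clip(data.xc.std(axis=0), 0.05, None))
                yk = data.y
            if self.task == "regression":
                st.beta1[k] = float(np.mean(yk))
            else:
                p = float(np.clip(np.mean(yk), 0.05, 0.95))
                st.beta1[k] = float(np.log(p / (1 - p)))
            for j, c in enumerate(data.n_categories):
                if c > 1:
                    freq = np.bincount(data.disc_codes[j][rows], minlength=c) + 1.0
                    st.phi_raw[j][k] = raw_from_simplex(freq / freq.sum())
        st.m += rng.normal(0.0, jitter, st.m.shape)
        st.beta1 += rng.normal(0.0, jitter, st.beta1.shape)
        st.refresh_all()

    # --------------------------------------------------------------- one sweep
    def sweep(self, rng: np.random.Generator) -> None:
        st, data, temp = self.state, self.data, self.temp
        K, d = self.K, data.d

        # mixture weights (stick-breaking raw); only log_pi changes
        if K > 1:
            M_base = st.cont3.sum(axis=2) + st.disc + st.resp
            for idx in range(K - 1):
                def logp(v, idx=idx):
                    raw = st.alpha.copy()
                    raw[idx] = v
                    pi, jac = simplex_from_raw(raw)
                    log_pi = np.log(np.clip(pi, 1e-300, None))
                    M = M_base + log_pi[None, :]
                    a = M.max(axis=1)
                    ll = float(np.sum(a + np.log(np.exp(M - a[:, None]).sum(axis=1))))
                    return jac + temp * ll

                x0 = st.alpha[idx]
                st.alpha[idx], _ = slice_sample_step(
                    x0, logp, logp(x0), 1.0, rng
                )
            pi, _ = simplex_from_raw(st.alpha)
            st.log_pi = np.log(np.clip(pi, 1e-300, None))

        for k in range(K):
            rest = st.rest_of(k)
            base_disc_resp = st.disc[:, k] + st.resp[:, k] + st.log_pi[k]

            # continuous means and log-sds
            for j in range(d):
                others = st.cont3[:, k, :].sum(axis=1) - st.cont3[:, k, j]
                xj = data.xc[:, j]

                def logp_m(v, j=j):
                    s = np.exp(st.log_s[k, j])
                    z = (xj - v) / s
                    term = -0.5 * _LOG2PI - st.log_s[k, j] - 0.5 * z * z
                    col = base_disc_resp + others + term
                    return -0.5 * (v / 5.0) ** 2 + temp * _loglik_from_rest(rest, col)

                x0 = st.m[k, j]
                st.m[k, j], _ = slice_sample_step(x0, logp_m, logp_m(x0), 1.0, rng)

                def logp_s(v, j=j):
                    s = np.exp(v)
                    z = (xj - st.m[k, j]) / s
                    term = -0.5 * _LOG2PI - v - 0.5 * z * z
                    col = base_disc_resp + others + term
                    pri = -np.log1p((s / 2.5) ** 2) + v
                    return pri + temp * _loglik_from_rest(rest, col)

                x0 = st.log_s[k, j]
                st.log_s[k, j], _ = slice_sample_step(x0, logp_s, logp_s(x0), 0.7, rng)
                st._refresh_cont(k, j)

            # categorical probabilities
            cont_k = st.cont3[:, k, :].sum(axis=1)
            for j, c in enumerate(data.n_categories):
                if c <= 1:
                    continue
                codes = data.disc_codes[j]
                disc_others = st.disc[:, k] - st.log_phi[j][k][codes]
                base = st.log_pi[k] + cont_k + st.resp[:, k] + disc_others
                for idx in range(c - 1):
                    def logp_phi(v, j=j, idx=idx):
                        raw = st.phi_raw[j][k].copy()
                        raw[idx] = v
                        phi, jac = simplex_from_raw(raw)
                        lphi = np.log(np.clip(phi, 1e-300, None))
                        col = base + lphi[codes]
                        return jac + temp * _loglik_from_rest(rest, col)

                    x0 = st.phi_raw[j][k][idx]
                    st.phi_raw[j][k][idx], _ = slice_sample_step(
                        x0, logp_phi, logp_phi(x0), 1.0, rng
                    )
                st._refresh_phi(j, k)
                st.disc[:, k] = disc_others + st.log_phi[j][k][codes]

            # response head: intercept and coefficients
            base = st.log_pi[k] + cont_k + st.disc[:, k]
            mu0 = st.mu[:, k]

            def resp_term(mu):
                if self.task == "regression":
                    z = (data.y - mu) / self.sigma
                    return -0.5 * _LOG2PI - np.log(self.sigma) - 0.5 * z * z
                return np.where(data.y > 0.5, log_expit(mu), log_expit(-mu))

            def logp_b1(v):
                mu = mu0 + (v - st.beta1[k])
                col = base + resp_term(mu)
                if self.task == "regression":
                    pri = -0.5 * ((v - self.y_mean) / (5.0 * max(self.y_std, 1e-8))) ** 2
                else:
                    pri = -0.5 * (v / 5.0) ** 2
                return pri + temp * _loglik_from_rest(rest, col)

            x0 = st.beta1[k]
            w_b = max(self.y_std, 0.5) if self.task == "regression" else 1.0
            st.beta1[k], _ = slice_sample_step(x0, logp_b1, logp_b1(x0), w_b, rng)
            mu0 = mu0 + (st.beta1[k] - x0)

            for j in range(d):
                xj = data.xc[:, j]

                def logp_ec(v, j=j):
                    mu = mu0 + (v - st.eta_c[k, j]) * xj
                    col = base + resp_term(mu)
                    return -abs(v) + temp * _loglik_from_rest(rest, col)

                x0 = st.eta_c[k, j]
                st.eta_c[k, j], _ = slice_sample_step(x0, logp_ec, logp_ec(x0), 1.0, rng)
                mu0 = mu0 + (st.eta_c[k, j] - x0) * xj

            for q in range(data.p):
                xq = data.xd1h[:, q]

                def logp_ed(v, q=q):
                    mu = mu0 + (v - st.eta_d[k, q]) * xq
                    col = base + resp_term(mu)
                    return -abs(v) + temp * _loglik_from_rest(rest, col)

                x0 = st.eta_d[k, q]
                st.eta_d[k, q], _ = slice_sample_step(x0, logp_ed, logp_ed(x0), 1.0, rng)
                mu0 = mu0 + (st.eta_d[k, q] - x0) * xq

            st.mu[:, k] = mu0
            st._refresh_resp(k)

    # ------------------------------------------------------------------- run
    def run(
        self,
        iterations: int,
        warmup: int,
        rng: np.random.Generator,
        jitter: float = 0.05,
    ) -> dict:
        """One chain; returns post-warmup draws on the constrained scale."""
        data, K = self.data, self.K
        self.initialize(rng, jitter=jitter)
        n_keep = iterations - warmup
        if n_keep <= 0:
            raise ValueError("iterations must exceed warmup")
        st = self.state
        out = {
            "pi": np.empty((n_keep, K)),
            "m": np.empty((n_keep, K, data.d)),
            "var": np.empty((n_keep, K, data.d)),
            "phi": [np.empty((n_keep, K, c)) for c in data.n_categories],
            "beta1": np.empty((n_keep, K)),
            "eta_cont": np.empty((n_keep, K, data.d)),
            "eta_disc": np.empty((n_keep, K, data.p)),
            "loglik": np.empty(n_keep),
        }
        for it in range(iterations):
            self.sweep(rng)
            if it >= warmup:
                t = it - warmup
                out["pi"][t] = np.exp(st.log_pi)
                out["m"][t] = st.m
                out["var"][t] = np.exp(2.0 * st.log_s)
                for j in range(len(data.n_categories)):
                    out["phi"][j][t] = np.exp(st.log_phi[j])
                out["beta1"][t] = st.beta1
                out["eta_cont"][t] = st.eta_c
                out["eta_disc"][t] = st.eta_d
                out["loglik"][t] = st.loglik()
        return out


# ------------------------------------------------------------------ diagnostics
def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction for one scalar.

    ``chains``: (n_chains, n_draws). Returns NaN when draws are constant.
    """
    n_chains, n = chains.shape
    half = n // 2
    if half < 2:
        return float("nan")
    halves = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, nn = halves.shape
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = nn * means.var(ddof=1)
    if W <= 1e-300:
        return float("nan")
    var_plus = (nn - 1) / nn * W + B / nn
    return float(np.sqrt(var_plus / W))
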