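"""Synthetic benchmark data.

Two generators back the whole test surface without any external data:

* :func:`generate_synthetic3d` — the 3D benchmark: three trivariate
  normal clusters with response ``y = x1 + x2 + x3 + Normal(0, 2)``.
  Two of the default clusters overlap heavily while the third sits far
  away, so a mixture fitted to the data resolves two effective
  components, and the straight line between typical high- and
  low-response points crosses a low-density gap — the situation the
  density-aware planner exists for.
* :func:`generate_mixture_table` — configurable health-checkup-like
  mixed tables (continuous + discrete columns, planted missingness) from
  an explicit :class:`MixtureSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml

from .dataset import Dataset
from .schema import Variable, VariableSchema


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: tuple[float, ...]
    covariance: tuple[tuple[float, ...], ...]
    #: per-discrete-variable category probabilities, keyed by variable name
    categorical: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self):
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (len(self.mean), len(self.mean)):
            raise ValueError("covariance shape does not match mean dimension")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() <= 0:
            raise ValueError("covariance must be positive definite")
        for name, probs in self.categorical.items():
            if abs(sum(probs) - 1.0) > 1e-8:
                raise ValueError(
                    f"categorical table for {name!r} does not sum to 1"
                )


@dataclass(frozen=True)
class ResponseRule:
    """How the response is computed from the continuous coordinates.

    ``linear-sum`` uses unit coefficients; ``custom`` uses the supplied
    vector. For a binary task the continuous response is thresholded.
    """

    kind: Literal["linear-sum", "custom"] = "linear-sum"
    coefficients: Optional[tuple[float, ...]] = None
    noise_sd: float = 2.0
    threshold: Optional[float] = None  # binary response when set

    def apply(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "linear-sum":
            coef = np.ones(x.shape[1])
        else:
            if self.coefficients is None:
                raise ValueError("custom response rule requires coefficients")
            coef = np.asarray(self.coefficients, dtype=float)
        y = x @ coef + rng.normal(0.0, self.noise_sd, size=len(x))
        if self.threshold is not None:
            y = (y > self.threshold).astype(float)
        return y


@dataclass(frozen=True)
class MixtureSpec:
    components: tuple[MixtureComponent, ...]
    response: ResponseRule = field(default_factory=ResponseRule)
    #: fixed per-component sample sizes (deterministic, not multinomial)
    sizes: tuple[int, ...] = ()

    def __post_init__(self):
        dims = {len(c.mean) for c in self.components}
        if len(dims) != 1:
            raise ValueError("all components must share one dimension")
        if self.sizes and len(self.sizes) != len(self.components):
            raise ValueError("sizes must match the number of components")

    @property
    def dim(self) -> int:
        return len(self.components[0].mean)

    def to_dict(self) -> dict:
        return {
            "components": [
                {
                    "weight": c.weight,
                    "mean": list(c.mean),
                    "covariance": [list(r) for r in c.covariance],
                    "categorical": {k: list(v) for k, v in c.categorical.items()},
                }
                for c in self.components
            ],
            "response": {
                "kind": self.response.kind,
                "coefficients": list(self.response.coefficients)
                if self.response.coefficients
                else None,
                "noise_sd": self.response.noise_sd,
                "threshold": self.response.threshold,
            },
            "sizes": list(self.sizes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureSpec":
        return cls(
            components=tuple(
                MixtureComponent(
                    weight=c["weight"],
                    mean=tuple(c["mean"]),
                    covariance=tuple(tuple(r) for r in c["covariance"]),
                    categorical={
                        k: tuple(v) for k, v in c.get("categorical", {}).items()
                    },
                )
                for c in d["components"]
            ),
            response=ResponseRule(
                kind=d["response"].get("kind", "linear-sum"),
                coefficients=tuple(d["response"]["coefficients"])
                if d["response"].get("coefficients")
                else None,
                noise_sd=d["response"].get("noise_sd", 2.0),
                threshold=d["response"].get("threshold"),
            ),
            sizes=tuple(d.get("sizes", ())),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "MixtureSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# --------------------------------------------------------------------------
# the 3D benchmark
# --------------------------------------------------------------------------

#: default cluster layout: two heavily overlapping components (1.2 sigma
#: apart, resolved as a single effective cluster) plus one distant one
BENCH3D_MEANS = ((0.0, 0.0, 0.0), (0.8, 0.8, 0.4), (4.0, 4.0, 3.0))


def synthetic3d_schema(intervenable: bool = True) -> VariableSchema:
    return VariableSchema(
        [
            Variable("x1", intervenable=intervenable, direction="decrease"),
            Variable("x2", intervenable=intervenable, direction="decrease"),
            Variable("x3", intervenable=intervenable, direction="decrease"),
            Variable("y", role="response"),
        ]
    )


def synthetic3d_spec(
    noise_sd: float = 2.0, n_per_component: int = 200
) -> MixtureSpec:
    eye = tuple(tuple(float(i == j) for j in range(3)) for i in range(3))
    return MixtureSpec(
        components=tuple(
            MixtureComponent(weight=1 / 3, mean=m, covariance=eye)
            for m in BENCH3D_MEANS
        ),
        response=ResponseRule(kind="linear-sum", noise_sd=noise_sd),
        sizes=(n_per_component,) * 3,
    )


def generate_synthetic3d(
    seed: int, n_per_component: int = 200, noise_sd: float = 2.0
) -> Dataset:
    """The 3D benchmark table: columns x1, x2, x3, y; 3 * n_per_component rows."""
    if n_per_component < 1:
        raise ValueError("n_per_component must be >= 1")
    spec = synthetic3d_spec(noise_sd=noise_sd, n_per_component=n_per_component)
    return generate_mixture_table(spec, synthetic3d_schema(), seed=seed)


# --------------------------------------------------------------------------
# generic mixed-table generator
# --------------------------------------------------------------------------


def generate_mixture_table(
    spec: MixtureSpec,
    schema: VariableSchema,
    seed: int,
    missing_rate: float = 0.0,
) -> Dataset:
    """Draw a mixed continuous/discrete table from ``spec``.

    Continuous explanatory columns come from the Gaussian mixture,
    discrete columns from the per-component categorical tables, the
    response from the response rule; missing cells are planted uniformly
    at ``missing_rate`` over explanatory cells.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    cont_vars = [v.name for v in schema.continuous_explanatory]
    disc_vars = schema.discrete_explanatory
    if spec.dim != len(cont_vars):
        raise ValueError(
            f"mixture dimension {spec.dim} != {len(cont_vars)} continuous explanatory variables"
        )
    if not spec.sizes:
        raise ValueError("spec.sizes must give per-component sample counts")
    rng = np.random.default_rng(seed)

    blocks_x, blocks_d, labels = [], [], []
    for c, (comp, size) in enumerate(zip(spec.components, spec.sizes)):
        x = rng.multivariate_normal(
            np.asarray(comp.mean, float),
            np.asarray(comp.covariance, float),
            size=size,
        )
        blocks_x.append(x)
        dcols = {}
        for var in disc_vars:
            probs = comp.categorical.get(var.name)
            if probs is None:
                raise ValueError(
                    f"component {c} lacks a categorical table for {var.name!r}"
                )
            idx = rng.choice(len(var.categories), size=size, p=np.asarray(probs))
            dcols[var.name] = np.asarray(var.categories, dtype=object)[idx]
        blocks_d.append(dcols)
        labels.append(np.full(size, c))

    x_all = np.vstack(blocks_x)
    y = spec.response.apply(x_all, rng)

    table = pd.DataFrame(x_all, columns=cont_vars)
    for var in disc_vars:
        table[var.name] = np.concatenate([b[var.name] for b in blocks_d])
    resp = schema.response
    if resp.kind == "discrete":
        cats = np.asarray(resp.categories, dtype=object)
        table[resp.name] = cats[y.astype(int)]
    else:
        table[resp.name] = y
    table = table[schema.names]

    if missing_rate > 0:
        expl = [v.name for v in schema.explanatory]
        plant = rng.random((len(table), len(expl))) < missing_rate
        for j, name in enumerate(expl):
            table.loc[plant[:, j], name] = np.nan
    return Dataset(table, schema)


def component_labels(spec: MixtureSpec) -> np.ndarray:
    """True component label per row, in generation order (for recovery tests)."""
    return np.concatenate(
        [np.full(s, c) for c, s in enumerate(spec.sizes)]
    )
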