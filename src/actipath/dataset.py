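"""Tabular dataset container: values, missingness mask, standardization record."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .schema import VariableSchema


@dataclass(frozen=True)
class Standardization:
    """Per-variable location/scale estimated on training rows only.

    Applies to continuous *explanatory* variables; the response is kept on
    its original scale throughout.
    """

    mean: dict[str, float]
    std: dict[str, float]

    def __post_init__(self) -> None:
        bad = [n for n, s in self.std.items() if not s > 0]
        if bad:
            raise ValueError(f"non-positive standard deviation for column(s) {bad}")


class Dataset:
    """Rows = instances, columns = schema variables.

    Values live in a :class:`pandas.DataFrame`; continuous columns are
    float64, discrete columns hold category labels (strings). Missing
    cells are tracked by an explicit boolean mask (True = missing) and
    mirrored as NaN/None in the value table, so numerical code never sees
    a sentinel number.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        schema: VariableSchema,
        mask: Optional[pd.DataFrame] = None,
        standardization: Optional[Standardization] = None,
    ):
        if list(values.columns) != schema.names:
            missing = [n for n in schema.names if n not in values.columns]
            if missing:
                raise ValueError(f"missing column(s): {missing}")
            values = values[schema.names]
        values = values.copy()
        for var in schema:
            col = values[var.name]
            if var.kind == "continuous":
                values[var.name] = pd.to_numeric(col, errors="raise").astype(float)
            else:
                labels = col.astype("object").where(col.notna(), None)
                bad = {
                    x for x in labels.dropna().unique() if str(x) not in var.categories
                }
                if bad:
                    raise ValueError(
                        f"column {var.name!r}: unknown categor{'ies' if len(bad) > 1 else 'y'} {sorted(map(str, bad))}"
                    )
                values[var.name] = labels.map(lambda x: None if x is None else str(x))
        if mask is None:
            mask = values.isna()
        else:
            mask = mask.astype(bool)
            if list(mask.columns) != schema.names or len(mask) != len(values):
                raise ValueError("mask shape/columns do not match the value table")
            mask = mask.set_axis(values.index, axis=0)
        values = values.mask(mask.to_numpy(), other=np.nan)
        self.values = values
        self.schema = schema
        self.mask = mask
        self.standardization = standardization

    # ------------------------------------------------------------------ basics
    def __len__(self) -> int:
        return len(self.values)

    @property
    def ids(self) -> list:
        return list(self.values.index)

    def copy(self, **overrides) -> "Dataset":
        kwargs = dict(
            values=self.values,
            schema=self.schema,
            mask=self.mask,
            standardization=self.standardization,
        )
        kwargs.update(overrides)
        return Dataset(**kwargs)

    def take(self, positions) -> "Dataset":
        """Row subset by integer position, order preserved."""
        return self.copy(
            values=self.values.iloc[positions], mask=self.mask.iloc[positions]
        )

    def has_missing(self) -> bool:
        return bool(self.mask.to_numpy().any())

    # --------------------------------------------------------------- accessors
    @property
    def y(self) -> pd.Series:
        return self.values[self.schema.response.name]

    def x_continuous(self) -> pd.DataFrame:
        return self.values[[v.name for v in self.schema.continuous_explanatory]]

    def x_discrete(self) -> pd.DataFrame:
        return self.values[[v.name for v in self.schema.discrete_explanatory]]

    def continuous_stats(self) -> Standardization:
        """Mean/sd of continuous explanatory columns (ddof=0), ignoring
        missing cells. Raises on degenerate (constant or all-missing) columns."""
        mean: dict[str, float] = {}
        std: dict[str, float] = {}
        for var in self.schema.continuous_explanatory:
            col = self.values[var.name].dropna()
            if len(col) < 2:
                raise ValueError(
                    f"column {var.name!r}: need >= 2 non-missing values for statistics"
                )
            s = float(col.std(ddof=0))
            if not s > 0:
                raise ValueError(f"column {var.name!r} is constant (sd = 0)")
            mean[var.name] = float(col.mean())
            std[var.name] = s
        return Standardization(mean=mean, std=std)

    def row_vector(self, position: int) -> Mapping[str, object]:
        """Single instance as a {name: value} mapping."""
        return dict(self.values.iloc[position])
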