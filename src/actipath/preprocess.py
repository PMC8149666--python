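"""Preprocessing applied before modelling.

Train/test splitting, standardization of continuous explanatory variables
by training-set mean and standard deviation, median/mode imputation, and
the 3-sigma outlier filter applied to the surrogate's training table.
All statistics are estimated on a ``stats_from`` dataset (the training
split) and applied to any target dataset, so no test-set leakage occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import Dataset, Standardization


def split_train_test(
    data: Dataset,
    train_fraction: float = 0.8,
    seed: int = 0,
    group_key: Optional[str] = None,
) -> tuple[Dataset, Dataset]:
    """Random, reproducible partition into training and test rows.

    ``floor(n * train_fraction)`` rows (or groups, when ``group_key`` is
    given — e.g. participant id, so one participant never straddles the
    split) go to training.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n = len(data)
    if group_key is None:
        perm = rng.permutation(n)
        n_train = int(np.floor(n * train_fraction))
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
    else:
        if group_key not in data.schema:
            raise ValueError(f"group_key column {group_key!r} not in schema")
        groups = data.values[group_key].to_numpy()
        uniq = pd.unique(groups)
        perm = rng.permutation(len(uniq))
        n_train_groups = int(np.floor(len(uniq) * train_fraction))
        train_groups = set(uniq[perm[:n_train_groups]])
        in_train = np.array([g in train_groups for g in groups])
        train_idx = np.flatnonzero(in_train)
        test_idx = np.flatnonzero(~in_train)
    return data.take(train_idx), data.take(test_idx)


def standardize(data: Dataset, stats_from: Dataset) -> Dataset:
    """(value - mean) / sd per continuous explanatory column.

    Statistics come from ``stats_from`` (the training split); discrete
    columns and the response are untouched. The fitted statistics are
    recorded on the result so :func:`destandardize` can round-trip.
    """
    stats = stats_from.continuous_stats()
    values = data.values.copy()
    for name in stats.mean:
        values[name] = (values[name] - stats.mean[name]) / stats.std[name]
    return data.copy(values=values, standardization=stats)


def destandardize(data: Dataset) -> Dataset:
    """Inverse of :func:`standardize`; round-trips to within 1e-12."""
    stats = data.standardization
    if stats is None:
        raise ValueError("dataset carries no standardization record")
    values = data.values.copy()
    for name in stats.mean:
        values[name] = values[name] * stats.std[name] + stats.mean[name]
    return data.copy(values=values, standardization=None)


def destandardize_value(name: str, value: float, stats: Standardization) -> float:
    if name in stats.mean:
        return value * stats.std[name] + stats.mean[name]
    return value


def impute_median(data: Dataset, stats_from: Dataset) -> Dataset:
    """Fill missing cells: continuous <- training median, discrete <- training mode."""
    values = data.values.copy()
    for var in data.schema:
        col = stats_from.values[var.name].dropna()
        if col.empty:
            raise ValueError(f"column {var.name!r} is fully missing in stats_from")
        if var.kind == "continuous":
            fill = float(col.median())
        else:
            # modal category; ties broken by category order in the schema
            counts = col.value_counts()
            top = counts[counts == counts.max()].index
            fill = next(c for c in var.categories if c in set(top))
        values[var.name] = values[var.name].fillna(fill)
    mask = values.isna()  # all False now
    return data.copy(values=values, mask=mask)


@dataclass
class OutlierReport:
    """Bookkeeping for the 3-sigma filter."""

    n_input: int
    n_removed: int
    removed_positions: list[int] = field(default_factory=list)
    triggering: dict[int, list[str]] = field(default_factory=dict)


def filter_outliers_3sigma(
    data: Dataset, stats_from: Dataset, n_sigma: float = 3.0
) -> tuple[Dataset, OutlierReport]:
    """Drop rows with any continuous explanatory value outside mean +/- 3 sd.

    Statistics are the training-set mean/sd; the response and discrete
    variables never trigger removal. Missing cells do not trigger removal.
    """
    stats = stats_from.continuous_stats()
    keep = np.ones(len(data), dtype=bool)
    triggering: dict[int, list[str]] = {}
    for name in stats.mean:
        col = data.values[name].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out = np.abs(col - stats.mean[name]) > n_sigma * stats.std[name]
        out &= ~np.isnan(col)
        for pos in np.flatnonzero(out):
            triggering.setdefault(int(pos), []).append(name)
        keep &= ~out
    removed = np.flatnonzero(~keep)
    report = OutlierReport(
        n_input=len(data),
        n_removed=len(removed),
        removed_positions=[int(i) for i in removed],
        triggering=triggering,
    )
    return data.take(np.flatnonzero(keep)), report
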