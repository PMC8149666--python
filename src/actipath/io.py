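"""Delimited-text readers/writers for datasets."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .dataset import Dataset
from .schema import VariableSchema

#: tokens (beyond the empty string) treated as missing on read
NA_TOKENS = ("", "NA", "NaN", "nan", "N/A", "null", "None")


def read_table(
    path: str | Path, schema: VariableSchema, sep: str = ","
) -> Dataset:
    """Read a delimited text file with a header row into a :class:`Dataset`.

    Continuous cells must parse as numbers, discrete cells must be known
    category labels; empty strings and NA tokens become missing. Errors
    name the offending row and column.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False, na_values=list(NA_TOKENS)
    )
    missing_cols = [n for n in schema.names if n not in raw.columns]
    if missing_cols:
        raise ValueError(f"{path.name}: missing column(s) {missing_cols}")
    raw = raw[schema.names]
    for var in schema:
        col = raw[var.name]
        if var.kind == "continuous":
            parsed = pd.to_numeric(col, errors="coerce")
            bad = col.notna() & parsed.isna()
            if bad.any():
                row = int(bad.idxmax())
                raise ValueError(
                    f"{path.name}: row {row}, column {var.name!r}: "
                    f"unparseable value {col[bad].iloc[0]!r}"
                )
            raw[var.name] = parsed
        else:
            known = col.isna() | col.isin(var.categories)
            if not known.all():
                row = int((~known).idxmax())
                raise ValueError(
                    f"{path.name}: row {row}, column {var.name!r}: "
                    f"unknown category {col[~known].iloc[0]!r}"
                )
    return Dataset(raw, schema)


def write_table(data: Dataset, path: str | Path, sep: str = ",") -> None:
    """Write the value table back as delimited text (missing cells empty)."""
    out = data.values.copy()
    out.to_csv(path, sep=sep, index=False, na_rep="")
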