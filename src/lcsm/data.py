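"""Wide-format longitudinal table.

One row per participant; occasion-indexed variables live in columns named
``{variable}_t{occasion}`` (e.g. ``fa_slf_t0``, ``speed_ipt_t2``,
``hm_t1``), time-invariant covariates in plain columns (``age_base``,
``education``, ``gender``).  Missing cells are NaN.  This is a thin
wrapper around a :class:`pandas.DataFrame` adding the column registry and
the row-retention rule used by full-information maximum likelihood.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["LongitudinalTable"]


class LongitudinalTable:
    """Wide per-participant table of occasion-indexed observed variables."""

    def __init__(self, df: pd.DataFrame, id_col: str | None = None):
        if id_col is not None and id_col in df.columns:
            df = df.set_index(id_col)
        self.df = df.copy()
        self.df.columns = [str(c) for c in self.df.columns]

    # -- column registry ------------------------------------------------
    def column(self, variable: str, occasion: float | None = None) -> str:
        """Resolve (variable, occasion) to a column name."""
        if occasion is None:
            name = variable
        else:
            occ = int(occasion) if float(occasion).is_integer() else occasion
            name = f"{variable}_t{occ}"
        if name not in self.df.columns:
            raise KeyError(f"no column {name!r} in table")
        return name

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def matrix(self, variables: Sequence[str]) -> np.ndarray:
        """Float matrix (rows x variables) with NaN for missing.

        Every requested variable must resolve to exactly one column.
        """
        missing = [v for v in variables if v not in self.df.columns]
        if missing:
            raise KeyError(f"model variables not found in table: {missing}")
        return self.df.loc[:, list(variables)].to_numpy(dtype=float)

    def retained(self, variables: Sequence[str]) -> "LongitudinalTable":
        """Drop rows with no observed value on any of ``variables``."""
        X = self.matrix(variables)
        keep = ~np.all(np.isnan(X), axis=1)
        return LongitudinalTable(self.df.loc[keep])

    def copy(self) -> "LongitudinalTable":
        return LongitudinalTable(self.df.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"LongitudinalTable({self.n_rows} rows, {len(self.df.columns)} columns)"


def as_table(data) -> LongitudinalTable:
    """Coerce a DataFrame or table to a LongitudinalTable."""
    if isinstance(data, LongitudinalTable):
        return data
    if isinstance(data, pd.DataFrame):
        return LongitudinalTable(data)
    raise TypeError(f"cannot interpret {type(data).__name__} as a longitudinal table")
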