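"""Feature tables and the two scaling rules used before plotting.

Dimensional features (lengths and widths of the cell, nucleus and
perinuclear ellipses) are scaled *jointly* to the interval [0.1, 1]:
the pooled minimum over all dimensional columns maps to 0.1 and the
pooled maximum to 1.0, so aspect ratios between the different dimensions
survive the rescale and no object vanishes at the low end.  All other
features are min-max scaled to [0, 1] per column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIM_LO = 0.1
DIM_SPAN = 0.9


class ScalingError(ValueError):
    """Raised for non-finite input or scaling-state misuse."""


@dataclass
class FeatureTable:
    """Named numeric matrix of per-sample measurements.

    Wraps a :class:`pandas.DataFrame` (rows = cells / populations,
    columns = named features) and records which columns are dimensional
    and whether the table has been scaled already.
    """

    data: pd.DataFrame
    dimensional_set: frozenset[str] = field(default_factory=frozenset)
    scaling_state: str = "raw"  # "raw" | "scaled"

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate column names: {dupes}")
        missing = set(self.dimensional_set) - set(self.data.columns)
        if missing:
            raise ValueError(f"dimensional columns not in table: {sorted(missing)}")

    @property
    def row_ids(self) -> list:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def numeric_columns(self) -> list[str]:
        return [c for c in self.data.columns
                if pd.api.types.is_numeric_dtype(self.data[c])]

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


def _require_finite(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ScalingError(f"non-finite values in {what}")


def scale_unit(column: np.ndarray) -> np.ndarray:
    """Min-max scale one column to [0, 1]; a constant column maps to 0.5."""
    column = np.asarray(column, dtype=float)
    _require_finite(column, "column")
    lo, hi = column.min(), column.max()
    if hi == lo:
        return np.full_like(column, 0.5)
    return (column - lo) / (hi - lo)


def scale_dimensional_values(
    columns: Sequence[np.ndarray],
) -> list[np.ndarray]:
    """Jointly scale dimensional columns to [0.1, 1] over their pooled range.

    v' = (v - min_all) / range_all * 0.9 + 0.1, with min/range taken over
    the pooled values of every column.  A zero pooled range maps all
    values to the interval midpoint 0.55.
    """
    arrays = [np.asarray(c, dtype=float) for c in columns]
    if not arrays:
        raise ScalingError("need at least one dimensional column")
    pooled = np.concatenate([a.ravel() for a in arrays])
    _require_finite(pooled, "dimensional columns")
    lo, hi = pooled.min(), pooled.max()
    if hi == lo:
        return [np.full_like(a, (DIM_LO + 1.0) / 2.0) for a in arrays]
    return [(a - lo) / (hi - lo) * DIM_SPAN + DIM_LO for a in arrays]


def scale_table(
    table: FeatureTable,
    columns: Iterable[str] | None = None,
) -> FeatureTable:
    """Scale a raw table: dimensional columns jointly, others per column.

    Parameters
    ----------
    table:
        Raw feature table; re-scaling an already scaled table is rejected.
    columns:
        Columns to scale (default: all numeric columns).
    """
    if table.scaling_state == "scaled":
        raise ScalingError("table is already scaled")
    cols = list(columns) if columns is not None else table.numeric_columns()
    unknown = set(cols) - set(table.columns)
    if unknown:
        raise ScalingError(f"unknown columns: {sorted(unknown)}")
    out = table.data.copy()
    dim_cols = [c for c in cols if c in table.dimensional_set]
    if dim_cols:
        scaled = scale_dimensional_values([table.column(c) for c in dim_cols])
        for name, vals in zip(dim_cols, scaled):
            out[name] = vals
    for name in cols:
        if name not in table.dimensional_set:
            out[name] = scale_unit(table.column(name))
    return replace(table, data=out, scaling_state="scaled")


def clip_unit(values: np.ndarray, name: str = "") -> np.ndarray:
    """Clip user-supplied pre-scaled values into [0, 1] with a warning."""
    values = np.asarray(values, dtype=float)
    if (values < 0).any() or (values > 1).any():
        logger.warning("values outside [0, 1] clipped%s",
                       f" in {name!r}" if name else "")
        values = np.clip(values, 0.0, 1.0)
    return values
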