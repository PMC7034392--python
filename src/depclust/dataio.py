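"""Reading/writing respondent tables and the IQR careless-response screen.

A survey table is a respondent-by-item matrix of bounded integer scores
(for BDI-13: 13 items, each 0-3, total 0-39), optionally carrying named
demographic (categorical) and correlate (real-valued) columns.

The careless-response screen removes respondents whose per-respondent
statistic (default: total score) falls outside the Tukey fences
``[Q1 - m*IQR, Q3 + m*IQR]``. Quartiles use the linear-interpolation
convention (``numpy.percentile`` default), which is documented here
because it determines exactly which respondents are removed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponseMatrix",
    "SurveyTable",
    "SurveySchema",
    "FilterReport",
    "SchemaError",
    "read_survey",
    "write_survey",
    "total_scores",
    "iqr_filter",
    "default_bdi13_schema",
]


class SchemaError(ValueError):
    """A survey file or table violates its declared schema."""


@dataclass(frozen=True)
class ResponseMatrix:
    """n x m integer item-score matrix with per-item maxima.

    Parameters
    ----------
    values
        Integer array of shape ``(n_respondents, n_items)``.
    item_max
        Per-item maximum score, shape ``(n_items,)``. All 3 for BDI-13.
    """

    values: np.ndarray
    item_max: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise SchemaError("responses must be a non-empty 2-D matrix")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(values == np.floor(values)):
                raise SchemaError("item scores must be integers")
            values = values.astype(np.int64)
        item_max = np.asarray(self.item_max, dtype=np.int64)
        if item_max.shape != (values.shape[1],):
            raise SchemaError("item_max must have one entry per item")
        if np.any(values < 0) or np.any(values > item_max):
            bad = np.argwhere((values < 0) | (values > item_max))[0]
            raise SchemaError(
                f"item score out of range at row {bad[0]}, item column {bad[1]}: "
                f"value {values[bad[0], bad[1]]} not in [0, {item_max[bad[1]]}]"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "item_max", item_max)

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def score_max(self) -> int:
        """Maximum possible total score (39 for BDI-13)."""
        return int(self.item_max.sum())


def total_scores(matrix: ResponseMatrix) -> np.ndarray:
    """Per-respondent total scores (row sums), the input to norm cutoffs."""
    return matrix.values.sum(axis=1)


@dataclass(frozen=True)
class SurveyTable:
    """Respondent identifiers, item responses, and optional covariates."""

    ids: np.ndarray
    responses: ResponseMatrix
    demographics: pd.DataFrame | None = None
    correlates: pd.DataFrame | None = None

    def __post_init__(self):
        ids = np.asarray(self.ids)
        if ids.shape != (self.responses.n_respondents,):
            raise SchemaError("ids must have one entry per respondent")
        if len(np.unique(ids)) != len(ids):
            dupes = pd.Series(ids)
            dupes = dupes[dupes.duplicated()].unique()[:5]
            raise SchemaError(f"duplicate respondent ids: {list(dupes)}")
        for name, df in (("demographics", self.demographics), ("correlates", self.correlates)):
            if df is not None and len(df) != len(ids):
                raise SchemaError(f"{name} length does not match respondent count")
        object.__setattr__(self, "ids", ids)

    @property
    def n(self) -> int:
        return self.responses.n_respondents

    def subset(self, mask_or_index) -> "SurveyTable":
        """Row subset preserving original order of the selected rows."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SurveyTable(
            ids=self.ids[idx],
            responses=ResponseMatrix(self.responses.values[idx], self.responses.item_max),
            demographics=None if self.demographics is None
            else self.demographics.iloc[idx].reset_index(drop=True),
            correlates=None if self.correlates is None
            else self.correlates.iloc[idx].reset_index(drop=True),
        )


@dataclass(frozen=True)
class SurveySchema:
    """Column mapping for reading a survey CSV."""

    id_col: str = "id"
    item_cols: tuple[str, ...] = tuple(f"item_{j}" for j in range(1, 14))
    item_max: tuple[int, ...] | int = 3
    demographic_cols: tuple[str, ...] = ()
    correlate_cols: tuple[str, ...] = ()

    def item_max_array(self) -> np.ndarray:
        if isinstance(self.item_max, int):
            return np.full(len(self.item_cols), self.item_max, dtype=np.int64)
        return np.asarray(self.item_max, dtype=np.int64)


def default_bdi13_schema(
    demographic_cols: Sequence[str] = (), correlate_cols: Sequence[str] = ()
) -> SurveySchema:
    """Schema for the 13-item short-form BDI: columns id, item_1..item_13."""
    return SurveySchema(
        demographic_cols=tuple(demographic_cols), correlate_cols=tuple(correlate_cols)
    )


def read_survey(path, schema: SurveySchema | None = None) -> SurveyTable:
    """Read a survey CSV into a validated :class:`SurveyTable`.

    Rows with missing, non-integer, or out-of-range item scores are
    rejected with a row-level diagnostic; no imputation is performed.
    """
    schema = schema or SurveySchema()
    df = pd.read_csv(path)
    missing = [c for c in (schema.id_col, *schema.item_cols,
                           *schema.demographic_cols, *schema.correlate_cols)
               if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    items = df[list(schema.item_cols)]
    if items.isna().any().any():
        r, c = np.argwhere(items.isna().to_numpy())[0]
        raise SchemaError(
            f"missing item response at row {r}, column {schema.item_cols[c]}"
        )
    vals = items.to_numpy()
    if not np.all(vals == np.floor(vals.astype(float))):
        r, c = np.argwhere(vals != np.floor(vals.astype(float)))[0]
        raise SchemaError(
            f"non-integer item score at row {r}, column {schema.item_cols[c]}"
        )
    vals = vals.astype(np.int64)
    item_max = schema.item_max_array()
    bad = (vals < 0) | (vals > item_max)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise SchemaError(
            f"item score out of range at row {r}, column {schema.item_cols[c]}: "
            f"value {vals[r, c]} not in [0, {item_max[c]}]"
        )

    return SurveyTable(
        ids=df[schema.id_col].to_numpy(),
        responses=ResponseMatrix(vals, item_max),
        demographics=df[list(schema.demographic_cols)].reset_index(drop=True)
        if schema.demographic_cols else None,
        correlates=df[list(schema.correlate_cols)].astype(float).reset_index(drop=True)
        if schema.correlate_cols else None,
    )


def write_survey(table: SurveyTable, path, schema: SurveySchema | None = None) -> None:
    """Write a :class:`SurveyTable` back to CSV (inverse of :func:`read_survey`)."""
    schema = schema or SurveySchema()
    if len(schema.item_cols) != table.responses.n_items:
        schema = dataclasses.replace(
            schema,
            item_cols=tuple(f"item_{j}" for j in range(1, table.responses.n_items + 1)),
        )
    df = pd.DataFrame({schema.id_col: table.ids})
    for j, col in enumerate(schema.item_cols):
        df[col] = table.responses.values[:, j]
    if table.demographics is not None:
        for col in table.demographics.columns:
            df[col] = table.demographics[col].to_numpy()
    if table.correlates is not None:
        for col in table.correlates.columns:
            df[col] = table.correlates[col].to_numpy()
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class FilterReport:
    """Accounting for one pass of the IQR screen; counts always reconcile."""

    n_input: int
    n_removed: int
    n_retained: int
    lower_fence: float
    upper_fence: float
    removed_ids: list = field(default_factory=list)
    statistic_name: str = "total_score"

    def __post_init__(self):
        if self.n_input != self.n_removed + self.n_retained:
            raise ValueError("filter counts do not reconcile")
        if self.lower_fence > self.upper_fence:
            raise ValueError("lower fence exceeds upper fence")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["removed_ids"] = [x.item() if hasattr(x, "item") else x for x in d["removed_ids"]]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def iqr_filter(
    table: SurveyTable,
    multiplier: float = 1.5,
    statistic: str = "total_score",
) -> tuple[SurveyTable, FilterReport]:
    """Remove respondents whose statistic lies outside the Tukey fences.

    ``multiplier=math.inf`` disables the filter (fences at +-inf). A second
    pass re-computes fences on the retained sample and may remove more
    respondents; the screen is not idempotent by design.
    """
    if table.n < 4:
        raise ValueError("IQR filter requires at least 4 respondents")
    if statistic != "total_score":
        raise ValueError(f"unknown filter statistic: {statistic!r}")
    stat = total_scores(table.responses).astype(float)
    if math.isinf(multiplier):
        lower, upper = -math.inf, math.inf
    else:
        q1, q3 = np.percentile(stat, [25, 75])  # linear interpolation
        iqr = q3 - q1
        lower, upper = q1 - multiplier * iqr, q3 + multiplier * iqr
    keep = (stat >= lower) & (stat <= upper)
    report = FilterReport(
        n_input=table.n,
        n_removed=int((~keep).sum()),
        n_retained=int(keep.sum()),
        lower_fence=float(lower),
        upper_fence=float(upper),
        removed_ids=list(table.ids[~keep]),
        statistic_name=statistic,
    )
    return table.subset(keep), report
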