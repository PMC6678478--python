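"""Read, validate, summarise and standardise site x factor survey tables.

A survey table holds one row per monitoring site and one column per
aquatic factor (canonical schema in :mod:`bloomlasso.schema`).  All
regressions operate on mean-centred, unit-variance columns, so this
module also owns the (de)standardisation transform and keeps the centre
and scale so coefficients can be reported on either scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schema import FACTORS, NONNEGATIVE, UNITS, normalize_factor

log = logging.getLogger(__name__)


class SurveyError(ValueError):
    """Base class for survey-table validation failures."""


class SchemaError(SurveyError):
    """A required factor column is missing or duplicated."""


class ParseError(SurveyError):
    """A cell could not be parsed as a finite number."""


class SizeError(SurveyError):
    """Fewer sites than the minimum the statistics require."""


class DegenerateColumnError(SurveyError):
    """A column has zero variance and cannot be standardised."""


@dataclass
class SurveyTable:
    """Validated site x factor measurement table.

    Attributes
    ----------
    data : pandas.DataFrame
        One row per site (index = site id), columns in canonical factor
        order, all cells finite floats.
    units : dict
        Unit string per factor.
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=lambda: dict(UNITS))

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def factor_names(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def validate(self) -> "SurveyTable":
        if self.data.shape[0] < 3:
            raise SizeError(
                f"survey needs at least 3 sites, got {self.data.shape[0]}"
            )
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            raise SchemaError("duplicate factor columns")
        arr = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ParseError(
                f"non-finite value at site {self.data.index[r]!r}, "
                f"factor {cols[c]!r}"
            )
        for name in cols:
            if name in NONNEGATIVE and (self.data[name] < 0).any():
                # physically nonnegative quantity; synthetic Gaussian
                # marginals may dip below zero, so warn rather than reject
                log.warning(
                    "negative values in nonnegative factor %r (%d cells)",
                    name, int((self.data[name] < 0).sum()),
                )
        return self


def read_survey(path: str | Path, schema: Sequence[str] = FACTORS) -> SurveyTable:
    """Read a survey CSV (header row, one column per schema factor).

    Column order in the file is irrelevant; spellings are normalised
    (Unicode minus, the TEP/TEMP variant).  Raises :class:`SchemaError`
    naming the first missing factor, :class:`ParseError` with row and
    column for non-numeric cells, :class:`SizeError` below 3 sites.
    """
    raw = pd.read_csv(path, dtype=str)
    raw.columns = [normalize_factor(c) for c in raw.columns]
    index_col = None
    if "site_id" in raw.columns:
        index_col = raw["site_id"]
        raw = raw.drop(columns=["site_id"])
    schema = [normalize_factor(s) for s in schema]
    for name in schema:
        if name not in raw.columns:
            raise SchemaError(f"missing factor column: {name!r}")
    raw = raw[list(schema)]
    parsed = {}
    for name in schema:
        col = pd.to_numeric(raw[name], errors="coerce")
        if col.isna().any():
            row = int(np.argmax(col.isna().to_numpy()))
            raise ParseError(
                f"non-numeric cell at row {row}, column {name!r}: "
                f"{raw[name].iloc[row]!r}"
            )
        parsed[name] = col.astype(float)
    data = pd.DataFrame(parsed)
    if index_col is not None:
        data.index = index_col.to_numpy()
    table = SurveyTable(data=data).validate()
    log.info("read survey: %d sites x %d factors from %s", table.n_sites, len(schema), path)
    return table


def write_survey(table: SurveyTable, path: str | Path) -> None:
    """Write a survey table as CSV with a leading site_id column."""
    out = table.data.copy()
    out.insert(0, "site_id", table.data.index)
    out.to_csv(path, index=False)


def summarize(table: SurveyTable) -> pd.DataFrame:
    """Per-factor max, mean, min and sample SD (n-1 denominator)."""
    d = table.data
    return pd.DataFrame(
        {
            "max": d.max(),
            "mean": d.mean(),
            "min": d.min(),
            "sd": d.std(ddof=1),
        }
    )


@dataclass
class StandardizedTable:
    """Mean-centred, unit-sample-variance view of a survey table."""

    values: pd.DataFrame
    center: pd.Series
    scale: pd.Series

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def factor_names(self) -> list[str]:
        return list(self.values.columns)

    def column(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy(dtype=float)

    def destandardize(self) -> SurveyTable:
        raw = self.values * self.scale + self.center
        return SurveyTable(data=raw)


def standardize(table: SurveyTable) -> StandardizedTable:
    """Centre each column and scale to unit sample variance (ddof=1).

    Raises :class:`DegenerateColumnError` naming any constant column.
    """
    center = table.data.mean()
    scale = table.data.std(ddof=1)
    dead = scale[scale <= 1e-10 * (1.0 + center.abs())]
    if len(dead):
        raise DegenerateColumnError(
            f"zero-variance column(s): {', '.join(map(repr, dead.index))}"
        )
    values = (table.data - center) / scale
    return StandardizedTable(values=values, center=center, scale=scale)


def standardize_vector(x: np.ndarray) -> np.ndarray:
    """Centre and scale a single vector to unit sample variance."""
    s = np.std(x, ddof=1)
    if s == 0.0:
        raise DegenerateColumnError("zero-variance vector")
    return (x - np.mean(x)) / s
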