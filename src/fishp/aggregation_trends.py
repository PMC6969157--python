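"""Country/continent/global aggregation, shares, and trend statistics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import SchemaError, read_region_map

FLUX_COLS = ("p_harvest_tg", "p_input_tg")


@dataclass
class RegionMap:
    """Country -> region lookup with optional validity windows.

    A country may appear several times with disjoint ``(year_start, year_end)``
    windows (inclusive, open-ended when missing), which supports era splits
    such as dissolved political entities mapping differently before and after
    a given year.
    """

    table: pd.DataFrame

    @classmethod
    def from_dict(cls, mapping: Mapping[str, str]) -> "RegionMap":
        return cls(pd.DataFrame({
            "country": list(mapping), "region": list(mapping.values()),
            "year_start": np.nan, "year_end": np.nan,
        }))

    @classmethod
    def read(cls, path) -> "RegionMap":
        return cls(read_region_map(path))

    def region_of(self, country: str, year: int) -> str | None:
        rows = self.table[self.table["country"] == country]
        for row in rows.itertuples(index=False):
            start = getattr(row, "year_start", np.nan)
            end = getattr(row, "year_end", np.nan)
            if (pd.isna(start) or year >= start) and (pd.isna(end) or year <= end):
                return row.region
        return None


def _with_net(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["p_net_tg"] = df["p_harvest_tg"] - df["p_input_tg"]
    return df


def aggregate(records: pd.DataFrame, region_map: RegionMap | None = None,
              level: str = "global") -> pd.DataFrame:
    """Sum record-level fluxes per year at the requested level.

    Returns columns (unit, year, p_harvest_tg, p_input_tg, p_net_tg). Sums
    are exact, so global equals the sum over continents equals the sum over
    countries.
    """
    records = records.copy()
    if level == "global":
        records["unit"] = "global"
    elif level == "country":
        records["unit"] = records["country"]
    elif level == "continent":
        if region_map is None:
            raise SchemaError("continent aggregation requires a region map")
        pairs = records[["country", "year"]].drop_duplicates()
        lut = {(c, y): region_map.region_of(c, int(y))
               for c, y in pairs.itertuples(index=False, name=None)}
        unmapped = sorted({c for (c, y), r in lut.items() if r is None})
        if unmapped:
            raise SchemaError(f"countries missing from region map: {unmapped}")
        records["unit"] = [lut[(c, y)] for c, y in
                           zip(records["country"], records["year"])]
    else:
        raise SchemaError(f"unknown aggregation level {level!r}")
    out = records.groupby(["unit", "year"], as_index=False)[list(FLUX_COLS)].sum()
    return _with_net(out)


def shares(records: pd.DataFrame, dimension: str,
           flux: str = "p_harvest_tg") -> pd.DataFrame:
    """Per-year fractional shares of ``flux`` across ``dimension`` categories.

    Shares sum to one per year; years with a zero denominator come out as
    missing values.
    """
    pivot = records.pivot_table(index="year", columns=dimension, values=flux,
                                aggfunc="sum", fill_value=0.0)
    totals = pivot.sum(axis=1)
    out = pivot.div(totals, axis=0)
    out[totals == 0] = np.nan
    return out


def find_peak(series: pd.Series) -> tuple[int, float]:
    """(year, value) of the series maximum; ties break to the earliest year."""
    if len(series) == 0:
        raise SchemaError("empty series")
    series = series.sort_index()
    values = series.to_numpy(float)
    i = int(np.argmax(values))  # argmax returns the first maximum
    return int(series.index[i]), float(values[i])


def find_zero_crossing(series: pd.Series) -> int | None:
    """First year from which the series is negative through its end.

    A single negative dip followed by recovery does not count; the sign must
    persist. Returns ``None`` when the series never turns persistently
    negative (a "beyond range" outcome).
    """
    if len(series) == 0:
        raise SchemaError("empty series")
    series = series.sort_index()
    neg = series.to_numpy(float) < 0
    suffix_neg = np.logical_and.accumulate(neg[::-1])[::-1]
    idx = np.flatnonzero(suffix_neg)
    if idx.size == 0:
        return None
    return int(series.index[idx[0]])


def format_crossing(year: int | None, last_year: int) -> str:
    """Render a crossing year, using the ``> last_year`` convention when the
    series never turns persistently negative."""
    return f"> {last_year}" if year is None else str(year)
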