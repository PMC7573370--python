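"""Per-plant trait time series and the dynamic traits derived from them.

For a static trait SI sampled on days t1 < t2 within a growth window:

* growth rate      GR = (SI(t2) − SI(t1)) / (t2 − t1)       — trait units/day
* accumulation     AC = Σ_{t=t1..t2} SI(t) / (t2 − t1)      — trait units

The Σ runs over *integer days* t1..t2 inclusive, with SI linearly
interpolated between sampled days (the default ``mode='daily'``); AC is
therefore essentially the average daily trait level over the window, up to
an (n+1)/n factor from the inclusive endpoints.  ``mode='sampled'`` instead
sums only the sampled acquisition days, for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TraitSeries", "DynamicTraits", "growth_rate",
           "accumulation_rate", "dynamic_traits", "assemble_series"]


@dataclass
class TraitSeries:
    """One plant's static traits over its sampled days (strictly increasing)."""

    variety: str
    plant: str
    days: np.ndarray
    values: pd.DataFrame          # indexed by day, one column per trait
    missing_days: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if len(self.values) != len(self.days):
            raise ValueError("one trait vector per day required")


@dataclass
class DynamicTraits:
    window: tuple[float, float]
    gr: pd.Series                 # per-trait growth rate
    ac: pd.Series                 # per-trait accumulation rate


def _check_window(series: TraitSeries, t1: float, t2: float) -> None:
    if t1 >= t2:
        raise ValueError("t1 must be earlier than t2")
    for t in (t1, t2):
        if not np.any(np.isclose(series.days, t)):
            raise ValueError(
                f"day {t} is not a sampled day; no extrapolation is performed")


def growth_rate(series: TraitSeries, t1: float, t2: float) -> pd.Series:
    """Per-trait finite-difference growth rate over [t1, t2]."""
    _check_window(series, t1, t2)
    v1 = series.values.iloc[int(np.argmin(np.abs(series.days - t1)))]
    v2 = series.values.iloc[int(np.argmin(np.abs(series.days - t2)))]
    return (v2 - v1) / (t2 - t1)


def accumulation_rate(series: TraitSeries, t1: float, t2: float,
                      mode: str = "daily") -> pd.Series:
    """Per-trait accumulation rate Σ SI / (t2 − t1) over [t1, t2]."""
    _check_window(series, t1, t2)
    if mode == "daily":
        grid = np.arange(t1, t2 + 0.5)
        total = {
            c: np.interp(grid, series.days, series.values[c].to_numpy()).sum()
            for c in series.values.columns
        }
        return pd.Series(total) / (t2 - t1)
    if mode == "sampled":
        sel = (series.days >= t1 - 1e-9) & (series.days <= t2 + 1e-9)
        return series.values.iloc[np.nonzero(sel)[0]].sum() / (t2 - t1)
    raise ValueError("mode must be 'daily' or 'sampled'")


def dynamic_traits(series: TraitSeries, t1: float, t2: float,
                   mode: str = "daily") -> DynamicTraits:
    return DynamicTraits(
        window=(t1, t2),
        gr=growth_rate(series, t1, t2),
        ac=accumulation_rate(series, t1, t2, mode=mode),
    )


def assemble_series(table: pd.DataFrame) -> list[TraitSeries]:
    """Join per-day trait rows into per-plant series.

    ``table`` needs columns ``variety``, ``plant``, ``day`` plus trait
    columns.  Plants observed on fewer than two days are excluded with a
    warning; days missing relative to the union of all sampled days are
    recorded per series.  Input day order is irrelevant (sorted on output).
    """
    required = {"variety", "plant", "day"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    all_days = set(table["day"].unique())
    out: list[TraitSeries] = []
    for (variety, plant), grp in table.groupby(["variety", "plant"], sort=True):
        grp = grp.sort_values("day")
        if grp["day"].nunique() < 2:
            warnings.warn(
                f"plant ({variety}, {plant}) observed on <2 days; excluded",
                stacklevel=2)
            continue
        days = grp["day"].to_numpy(float)
        values = grp.drop(columns=["variety", "plant", "day"]).reset_index(
            drop=True)
        missing = tuple(sorted(int(d) for d in all_days - set(grp["day"])))
        out.append(TraitSeries(str(variety), str(plant), days, values,
                               missing_days=missing))
    return out
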