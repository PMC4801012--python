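"""Abundance time series and derived per-capita growth series.

An annual census series (year, count) is the common currency of the
pipeline: the demographic Allee-effect detector consumes the observed wolf
counts, the trajectory classifier consumes simulated ones, and the
synthetic generator produces them.  The derived quantity everywhere is the
per-capita growth rate into year t,

    pgr_t = ln(N_t / N_{t-1}),

paired with a log-abundance predictor (ln N_t by default; ln N_{t-1}
behind the ``predictor_lag`` switch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountSeries",
    "GrowthSeries",
    "CountSeriesError",
    "load_count_series",
    "compute_growth",
]


class CountSeriesError(ValueError):
    """Raised when a count series violates its invariants."""


@dataclass(frozen=True)
class CountSeries:
    """An annual abundance series for one measure of population size.

    Parameters
    ----------
    measure_id
        Label for the measure (e.g. ``"sls"``, ``"wisconsin"``,
        ``"packs"``, ``"territory_km2"`` or ``"synthetic"``).
    years
        Strictly increasing calendar or simulation years, no gaps.
    values
        Positive abundances (wolves, packs, or km² of occupied territory).
    units
        Carried as metadata only; all measures flow through the same code.
    """

    measure_id: str
    years: np.ndarray
    values: np.ndarray
    units: str = "wolves"
    allow_gaps: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or years.shape != values.shape:
            raise CountSeriesError("years and values must be 1-D and aligned")
        if len(years) < 2:
            raise CountSeriesError("a count series needs at least 2 years")
        dy = np.diff(years)
        if np.any(dy <= 0):
            bad = years[1:][dy <= 0][0]
            raise CountSeriesError(f"years not strictly increasing at {bad}")
        if not self.allow_gaps and np.any(dy > 1):
            bad = years[1:][dy > 1][0]
            raise CountSeriesError(
                f"gap in years before {bad}; pass allow_gaps=True to segment"
            )
        if np.any(values <= 0) or not np.all(np.isfinite(values)):
            bad = years[(values <= 0) | ~np.isfinite(values)][0]
            raise CountSeriesError(
                f"non-positive or non-finite count in year {bad}: "
                "log-growth is undefined"
            )

    def __len__(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "count": self.values})


@dataclass(frozen=True)
class GrowthSeries:
    """Per-capita growth observations derived from a :class:`CountSeries`.

    ``pgr[i]`` is the growth into ``years[i]`` and ``ln_n[i]`` the log
    abundance used as its predictor.
    """

    years: np.ndarray
    ln_n: np.ndarray
    pgr: np.ndarray
    measure_id: str = "synthetic"
    predictor_lag: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "ln_n", np.asarray(self.ln_n, dtype=float))
        object.__setattr__(self, "pgr", np.asarray(self.pgr, dtype=float))
        if not (len(self.years) == len(self.ln_n) == len(self.pgr)):
            raise CountSeriesError("growth series fields must align")
        if not np.all(np.isfinite(self.pgr)):
            raise CountSeriesError("non-finite growth rate")

    def __len__(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "ln_n": self.ln_n, "pgr": self.pgr}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_count_series(
    path,
    measure_id: str,
    *,
    year_col: str = "year",
    count_col: str = "count",
    units: str = "wolves",
    allow_gaps: bool = False,
) -> CountSeries:
    """Read an annual census CSV (header required) into a CountSeries.

    Rows are sorted by year; duplicate years and non-positive counts raise
    :class:`CountSeriesError` naming the offending year.
    """
    df = pd.read_csv(path)
    missing = {year_col, count_col} - set(df.columns)
    if missing:
        raise CountSeriesError(f"missing column(s) {sorted(missing)} in {path}")
    df = df.sort_values(year_col)
    years = df[year_col].to_numpy()
    dup = pd.Series(years).duplicated()
    if dup.any():
        raise CountSeriesError(f"duplicate year {years[dup.to_numpy()][0]}")
    return CountSeries(
        measure_id=measure_id,
        years=years,
        values=df[count_col].to_numpy(dtype=float),
        units=units,
        allow_gaps=allow_gaps,
    )


def compute_growth(series: CountSeries, *, predictor_lag: int = 0) -> GrowthSeries:
    """Derive (ln N, pgr) pairs from consecutive annual counts.

    ``predictor_lag=0`` pairs pgr_t with ln(N_t) (the convention used for
    the wolf analysis); ``predictor_lag=1`` pairs it with ln(N_{t-1}), the
    classical Ricker-regression form, for sensitivity checks.  If the
    series permits gap years, growth is only computed within contiguous
    segments.
    """
    if predictor_lag not in (0, 1):
        raise ValueError("predictor_lag must be 0 or 1")
    years = series.years
    ln = np.log(series.values)
    contig = np.diff(years) == 1
    pgr = np.diff(ln)[contig]
    t_years = years[1:][contig]
    ln_pred = (ln[1:] if predictor_lag == 0 else ln[:-1])[contig]
    return GrowthSeries(
        years=t_years,
        ln_n=ln_pred,
        pgr=pgr,
        measure_id=series.measure_id,
        predictor_lag=predictor_lag,
    )
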