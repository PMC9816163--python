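"""Climate forcing series: monthly SST / aragonite saturation and sea-level rise.

The simulation consumes two kinds of forcing. ``ClimateSeries`` holds one
emission scenario's monthly sea-surface temperature (°C) and aragonite
saturation state Ω_Ar (dimensionless) over complete calendar years.
``SlrSeries`` holds cumulative sea-level rise (cm above the simulation-start
sea level) per year; rise is modelled as linear in time at a configurable
cm-per-decade rate, one series per labelled projection.

Model SST is bias-corrected against in-situ observations by shifting the
whole series so that a reference-month climatology (typically the August
mean over a buoy's deployment window) matches the observed one.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoverageError, InvalidParameterError

__all__ = [
    "ClimateSeries",
    "SlrSeries",
    "bias_correct_sst",
    "reference_month_mean",
    "build_slr_series",
    "read_climate_csv",
    "write_climate_csv",
    "read_slr_csv",
    "write_slr_csv",
]

SST_BOUNDS = (-2.0, 45.0)
OMEGA_BOUNDS = (0.0, 6.0)


@dataclass(frozen=True)
class ClimateSeries:
    """Monthly SST and Ω_Ar trajectory for one scenario.

    Parameters
    ----------
    scenario_label
        Free-text scenario name (e.g. ``"SSP5-8.5-like"``).
    years, months
        Parallel integer arrays; must form complete calendar years
        (January–December) with no gaps.
    sst
        Sea-surface temperature per month, °C.
    omega_ar
        Aragonite saturation state per month, dimensionless.
    """

    scenario_label: str
    years: np.ndarray
    months: np.ndarray
    sst: np.ndarray
    omega_ar: np.ndarray

    def __post_init__(self) -> None:
        for name in ("years", "months", "sst", "omega_ar"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        n = len(self.years)
        if not (len(self.months) == len(self.sst) == len(self.omega_ar) == n):
            raise InvalidParameterError("years, months, sst, omega_ar must have equal length")
        if n == 0 or n % 12 != 0:
            raise InvalidParameterError("climate series must contain complete calendar years")
        expected_months = np.tile(np.arange(1, 13), n // 12)
        if not np.array_equal(self.months, expected_months):
            raise InvalidParameterError("months must run January–December for every year")
        expected_years = np.repeat(np.arange(self.years[0], self.years[0] + n // 12), 12)
        if not np.array_equal(self.years, expected_years):
            raise InvalidParameterError("years must be consecutive with 12 entries each")
        if not np.all(np.isfinite(self.sst)) or not np.all(np.isfinite(self.omega_ar)):
            raise InvalidParameterError("sst and omega_ar must be finite")
        lo, hi = SST_BOUNDS
        if np.any(self.sst <= lo) or np.any(self.sst >= hi):
            raise InvalidParameterError(f"sst outside physical bounds {SST_BOUNDS}")
        lo, hi = OMEGA_BOUNDS
        if np.any(self.omega_ar <= lo) or np.any(self.omega_ar >= hi):
            raise InvalidParameterError(f"omega_ar outside physical bounds {OMEGA_BOUNDS}")

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    def covers(self, start_year: int, end_year: int) -> bool:
        return self.start_year <= start_year and end_year <= self.end_year

    def annual_means(self) -> pd.DataFrame:
        """Calendar-year means of SST and Ω_Ar, indexed by year."""
        df = pd.DataFrame({"year": self.years, "sst_c": self.sst, "omega_ar": self.omega_ar})
        return df.groupby("year").mean()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "month": self.months, "sst_c": self.sst, "omega_ar": self.omega_ar}
        )


@dataclass(frozen=True)
class SlrSeries:
    """Cumulative sea-level rise in cm above the start-year sea level."""

    years: np.ndarray
    cumulative_rise: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "cumulative_rise", np.asarray(self.cumulative_rise, dtype=float))
        if len(self.years) != len(self.cumulative_rise) or len(self.years) == 0:
            raise InvalidParameterError("years and cumulative_rise must be equal-length, non-empty")
        if not np.array_equal(self.years, np.arange(self.years[0], self.years[0] + len(self.years))):
            raise InvalidParameterError("years must be consecutive")
        if self.cumulative_rise[0] != 0.0:
            raise InvalidParameterError("cumulative rise must be 0 at the start year")
        if np.any(np.diff(self.cumulative_rise) < 0):
            raise InvalidParameterError("cumulative rise must be non-decreasing")

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    def rise_at(self, year: int) -> float:
        idx = int(year) - self.start_year
        if idx < 0 or idx >= len(self.years):
            raise CoverageError(f"year {year} outside SLR series {self.label!r}")
        return float(self.cumulative_rise[idx])


def bias_correct_sst(
    series: ClimateSeries, model_ref_mean: float, observed_ref_mean: float
) -> ClimateSeries:
    """Shift every monthly SST by ``observed_ref_mean − model_ref_mean``.

    Anchors a modelled series to an in-situ climatology: e.g. subtracting
    the model's August reference mean and adding the buoy-observed one.
    Ω_Ar is untouched.
    """
    if not (math.isfinite(model_ref_mean) and math.isfinite(observed_ref_mean)):
        raise InvalidParameterError("reference means must be finite")
    offset = observed_ref_mean - model_ref_mean
    return dataclasses.replace(series, sst=series.sst + offset)


def reference_month_mean(
    series: ClimateSeries, month_index: int, year_range: tuple[int, int]
) -> float:
    """Arithmetic mean of SST in one calendar month over an inclusive year range."""
    if not 1 <= month_index <= 12:
        raise InvalidParameterError("month_index must be in 1..12")
    lo, hi = year_range
    if lo > hi:
        raise InvalidParameterError("year_range must be (first, last) with first <= last")
    if not series.covers(lo, hi):
        raise CoverageError(f"series {series.scenario_label!r} does not cover {lo}–{hi}")
    mask = (series.months == month_index) & (series.years >= lo) & (series.years <= hi)
    if not mask.any():
        raise CoverageError("empty selection for reference month mean")
    return float(series.sst[mask].mean())


def build_slr_series(
    rate_cm_per_decade: float, start_year: int, end_year: int, label: str = ""
) -> SlrSeries:
    """Linear-in-time cumulative SLR: ``rate × (year − start) / 10`` cm."""
    if not math.isfinite(rate_cm_per_decade) or rate_cm_per_decade < 0:
        raise InvalidParameterError("SLR rate must be finite and non-negative")
    if end_year <= start_year:
        raise InvalidParameterError("end_year must exceed start_year")
    years = np.arange(start_year, end_year + 1)
    rise = rate_cm_per_decade * (years - start_year) / 10.0
    return SlrSeries(years=years, cumulative_rise=rise, label=label)


# -- CSV dialect: climate (year, month, sst_c, omega_ar); SLR (year, rise_cm) --

def write_climate_csv(series: ClimateSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_climate_csv(path, scenario_label: str | None = None) -> ClimateSeries:
    df = pd.read_csv(path)
    required = {"year", "month", "sst_c", "omega_ar"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"climate CSV missing columns: {sorted(missing)}")
    return ClimateSeries(
        scenario_label=scenario_label if scenario_label is not None else str(path),
        years=df["year"].to_numpy(int),
        months=df["month"].to_numpy(int),
        sst=df["sst_c"].to_numpy(float),
        omega_ar=df["omega_ar"].to_numpy(float),
    )


def write_slr_csv(series: SlrSeries, path) -> None:
    pd.DataFrame({"year": series.years, "rise_cm": series.cumulative_rise}).to_csv(path, index=False)


def read_slr_csv(path, label: str = "") -> SlrSeries:
    df = pd.read_csv(path)
    missing = {"year", "rise_cm"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"SLR CSV missing columns: {sorted(missing)}")
    return SlrSeries(
        years=df["year"].to_numpy(int), cumulative_rise=df["rise_cm"].to_numpy(float), label=label
    )
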