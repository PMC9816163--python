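"""Degree heating weeks, bleaching severity, and annual-severe-bleaching onset.

Thermal stress is accumulated as monthly "hotspots" — positive SST anomalies
above a local bleaching threshold (31.3 °C at a Florida-Keys inshore patch
reef). Hotspots summed over every rolling 3-consecutive-month window and
multiplied by 4.35 weeks/month give degree heating weeks (DHW, °C-weeks);
each year is characterised by its maximum windowed DHW. A year is classified
as *severe* bleaching at ≥ 8 DHW, *modest* at 4–8 DHW, and unstressed below.

Coral thermal adaptation is represented as a non-negative offset added to
the bleaching threshold before hotspot computation, so an adapted community
accumulates stress only above a higher temperature.

The onset of annual severe bleaching (ASB) is the first year from which
*every* remaining year in the projection is severe — a single hot year is
not onset.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .climate_forcing import ClimateSeries
from .errors import InvalidParameterError

__all__ = [
    "Severity",
    "ThermalConfig",
    "ThermalYear",
    "monthly_hotspots",
    "annual_max_dhw",
    "classify",
    "classify_years",
    "asb_onset_year",
]

DHW_WINDOW_MONTHS = 3


class Severity(str, enum.Enum):
    NONE = "none"
    MODEST = "modest"
    SEVERE = "severe"


@dataclass(frozen=True)
class ThermalConfig:
    """Bleaching-threshold and DHW classification parameters.

    ``bleaching_threshold`` is the local observed bleaching threshold in °C;
    ``adaptation_offset`` (°C) raises it to represent acquired thermal
    tolerance. ``weeks_per_month`` converts monthly °C-month sums to
    °C-weeks. ``asb_dhw``/``mb_dhw`` are the severe and modest bleaching
    bounds in °C-weeks.
    """

    bleaching_threshold: float = 31.3
    weeks_per_month: float = 4.35
    asb_dhw: float = 8.0
    mb_dhw: float = 4.0
    adaptation_offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.mb_dhw < self.asb_dhw:
            raise InvalidParameterError("require 0 <= mb_dhw < asb_dhw")
        if self.weeks_per_month <= 0:
            raise InvalidParameterError("weeks_per_month must be positive")
        if self.adaptation_offset < 0:
            raise InvalidParameterError("adaptation_offset must be non-negative")

    @property
    def effective_threshold(self) -> float:
        return self.bleaching_threshold + self.adaptation_offset


@dataclass(frozen=True)
class ThermalYear:
    """Annual-maximum DHW and (optionally) its bleaching classification."""

    year: int
    max_dhw: float
    severity: Severity | None = None

    def __post_init__(self) -> None:
        if self.max_dhw < 0:
            raise InvalidParameterError("max_dhw must be non-negative")


def monthly_hotspots(series: ClimateSeries, cfg: ThermalConfig) -> np.ndarray:
    """Positive monthly anomalies (°C) above the adaptation-shifted threshold."""
    return np.maximum(0.0, series.sst - cfg.effective_threshold)


def annual_max_dhw(series: ClimateSeries, cfg: ThermalConfig) -> list[ThermalYear]:
    """Annual maxima of 3-month rolling DHW.

    Rolling windows of 3 consecutive months may span year boundaries; a
    window is assigned to the calendar year in which it ends. Severity is
    left unset; see :func:`classify_years`.
    """
    hot = monthly_hotspots(series, cfg)
    if len(hot) < DHW_WINDOW_MONTHS:
        raise InvalidParameterError("need at least 3 months of data")
    window_sums = np.convolve(hot, np.ones(DHW_WINDOW_MONTHS), mode="valid")
    dhw = window_sums * cfg.weeks_per_month
    end_years = series.years[DHW_WINDOW_MONTHS - 1 :]
    out = []
    for year in range(series.start_year, series.end_year + 1):
        sel = dhw[end_years == year]
        if len(sel):
            out.append(ThermalYear(year=year, max_dhw=float(sel.max())))
    return out


def classify(max_dhw: float, cfg: ThermalConfig) -> Severity:
    """Bleaching severity of one year's maximum DHW.

    Boundary values go to the more severe class: exactly 8 DHW is severe,
    exactly 4 DHW is modest.
    """
    if max_dhw < 0:
        raise InvalidParameterError("max_dhw must be non-negative")
    if max_dhw >= cfg.asb_dhw:
        return Severity.SEVERE
    if max_dhw >= cfg.mb_dhw:
        return Severity.MODEST
    return Severity.NONE


def classify_years(years: list[ThermalYear], cfg: ThermalConfig) -> list[ThermalYear]:
    return [ThermalYear(y.year, y.max_dhw, classify(y.max_dhw, cfg)) for y in years]


def asb_onset_year(years: list[ThermalYear]) -> int | None:
    """First year from which every remaining year is severe; ``None`` if absent."""
    if not years:
        raise InvalidParameterError("empty thermal-year sequence")
    if any(y.severity is None for y in years):
        raise InvalidParameterError("severity must be classified before onset detection")
    onset = None
    for y in reversed(years):
        if y.severity is not Severity.SEVERE:
            break
        onset = y.year
    return onset
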