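"""Vertical reef accretion: RAP_max, accumulated height, and SLR pacing.

The annual carbonate budget (kg CaCO₃ m⁻² yr⁻¹) is converted to a maximum
vertical reef accretion potential

    RAP_max = (net production + sediment infill) / (ρ · (1 − porosity))

in mm yr⁻¹, with framework density ρ = 2.89 g cm⁻³ and porosity ≈ 30 % for
massive-coral-dominated assemblages. Sediment infill credits back a
fraction of bioeroded material reincorporated into the framework: 25 % of
parrotfish-produced sediment and 50 % of sediment from other macro
bioeroders (urchins, sponges); microborer loss is treated as fine-scale /
chemical and yields no reincorporable sediment (configurable). "Net
production" here is NCC, so erosion is not double-counted against infill
and negative budgets translate into framework loss.

Accumulated height is the running cumulative sum of RAP_max with the
present (simulation-start) reef height as datum. Keeping pace with
sea-level rise is judged on cumulative stocks: accumulated accretion (mm)
versus cumulative SLR (mm) — a reef that banked height can briefly
tolerate SLR rates exceeding its accretion rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate_forcing import SlrSeries
from .errors import ConfigurationError, CoverageError, InvalidParameterError

__all__ = [
    "AccretionConfig",
    "sediment_infill",
    "rap_max",
    "accumulated_height",
    "keep_pace_horizon",
]


@dataclass(frozen=True)
class AccretionConfig:
    """Framework density, porosity, and sediment reincorporation fractions."""

    carbonate_density: float = 2.89  # g cm^-3
    framework_porosity: float = 0.30
    parrotfish_sediment_reincorporation: float = 0.25
    other_bioeroder_sediment_reincorporation: float = 0.50
    microborer_sediment_reincorporation: float = 0.0

    def __post_init__(self) -> None:
        if self.carbonate_density <= 0:
            raise InvalidParameterError("carbonate density must be positive")
        if not 0 <= self.framework_porosity < 1:
            raise ConfigurationError("framework porosity must be in [0, 1)")
        for name in (
            "parrotfish_sediment_reincorporation",
            "other_bioeroder_sediment_reincorporation",
            "microborer_sediment_reincorporation",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise InvalidParameterError(f"{name} must be in [0, 1]")


def sediment_infill(
    erosion_parrotfish: float,
    erosion_urchin: float,
    erosion_sponge: float,
    cfg: AccretionConfig = AccretionConfig(),
    erosion_micro: float = 0.0,
) -> float:
    """Bioeroded sediment reincorporated into the framework, kg m⁻² yr⁻¹."""
    for flux in (erosion_parrotfish, erosion_urchin, erosion_sponge, erosion_micro):
        if flux < 0:
            raise InvalidParameterError("erosion fluxes must be non-negative magnitudes")
    return (
        cfg.parrotfish_sediment_reincorporation * erosion_parrotfish
        + cfg.other_bioeroder_sediment_reincorporation * (erosion_urchin + erosion_sponge)
        + cfg.microborer_sediment_reincorporation * erosion_micro
    )


def rap_max(
    net_production: float, infill: float, cfg: AccretionConfig = AccretionConfig()
) -> float:
    """Maximum vertical accretion potential, mm yr⁻¹ (negative = net loss).

    Unit chain: 1 kg m⁻² = 0.1 g cm⁻²; dividing by the effective density
    ρ(1 − porosity) in g cm⁻³ gives cm yr⁻¹; × 10 gives mm yr⁻¹.
    """
    effective_density = cfg.carbonate_density * (1.0 - cfg.framework_porosity)
    mass_g_cm2 = (net_production + infill) * 0.1
    return mass_g_cm2 / effective_density * 10.0


def accumulated_height(rap_series: np.ndarray) -> np.ndarray:
    """Running cumulative sum of annual RAP_max, mm above the present datum."""
    return np.cumsum(np.asarray(rap_series, dtype=float))


def keep_pace_horizon(
    years: np.ndarray, rap_series: np.ndarray, slr: SlrSeries
) -> int | None:
    """Last year through which accumulated accretion ≥ cumulative SLR.

    Both stocks are measured in mm at the END of each year, from the first
    common year: after year i the reef has banked the cumulative sum of
    RAP_max through i, and the sea has risen through i's full-year
    increment. Returns the last year Y such that the reef has not fallen
    behind in any year ≤ Y, or ``None`` if it falls behind in the very
    first year (so a zero-accretion reef under any positive SLR never
    keeps pace).
    """
    years = np.asarray(years, dtype=int)
    rap_series = np.asarray(rap_series, dtype=float)
    if len(years) != len(rap_series) or len(years) == 0:
        raise InvalidParameterError("years and rap_series must be equal-length, non-empty")
    common = np.intersect1d(years, slr.years)
    if len(common) == 0:
        raise CoverageError("accretion and SLR series share no years")
    start = int(common[0])
    mask = (years >= start) & (years <= common[-1])
    height_mm = np.cumsum(rap_series[mask])

    def rise_end_of_year(y: int) -> float:
        # cumulative_rise is anchored at the start of its first year, so the
        # end-of-year stock is the next year's value; extrapolate the final
        # annual increment at the series tail
        if y + 1 <= int(slr.years[-1]):
            return slr.rise_at(y + 1)
        if len(slr.years) > 1:
            last_increment = float(slr.cumulative_rise[-1] - slr.cumulative_rise[-2])
        else:
            last_increment = 0.0
        return float(slr.cumulative_rise[-1]) + last_increment * (y + 1 - int(slr.years[-1]))

    rise_mm = np.array([(rise_end_of_year(int(y)) - slr.rise_at(start)) * 10.0 for y in years[mask]])
    behind = height_mm < rise_mm
    if behind[0]:
        return None
    if not behind.any():
        return int(common[-1])
    first_fail = int(np.argmax(behind))
    return int(years[mask][first_fail - 1])
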