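"""Annual habitat-persistence simulation loop.

For each transect and each simulated year the engine applies, in a fixed
and test-pinned order: (1) baseline coral growth (halved in bleaching
years), (2) restoration planting scheduled for that year, (3) bleaching
mortality according to the year's severity, then (4) computes all carbonate
fluxes on the updated state with that year's mean SST and Ω_Ar. Mortality
runs last so that grown and freshly planted cover is exposed to its
planting-year bleaching — a conservative convention.

Bleaching severity comes from annual-maximum degree heating weeks of the
scenario's (bias-corrected) climate series under the scenario's adaptation
offset. The annual environment driving rate modification is the mean of the
12 monthly SST and Ω_Ar values of the calendar year.

Net community calcification (NCC, kg CaCO₃ m⁻² yr⁻¹) is production minus
erosion minus dissolution; the onset of net erosion is the first year from
which NCC stays negative to the end of the projection (a transient negative
year is not cessation of accretion). The engine is fully deterministic
given its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .climate_forcing import ClimateSeries
from .community import (
    MortalityTable,
    RestorationSchedule,
    TransectState,
    apply_bleaching_mortality,
    apply_growth,
    apply_restoration,
)
from .errors import CoverageError, InvalidParameterError
from .rates import (
    RateConfig,
    cca_production,
    coral_production,
    micro_erosion,
    parrotfish_erosion,
    sand_dissolution,
    sponge_erosion,
    urchin_erosion,
)
from .thermal_stress import Severity, ThermalConfig, ThermalYear, annual_max_dhw, classify_years

__all__ = [
    "AnnualFluxes",
    "ScenarioSpec",
    "BudgetTrajectory",
    "net_community_calcification",
    "step_year",
    "run_projection",
    "mean_trajectory",
    "onset_of_net_erosion",
]

NCC_TOL = 1e-9


@dataclass(frozen=True)
class AnnualFluxes:
    """One year's carbonate fluxes, kg CaCO₃ m⁻² yr⁻¹ (positive magnitudes)."""

    production_coral: float
    production_cca: float
    erosion_parrotfish: float
    erosion_urchin: float
    erosion_sponge: float
    erosion_micro: float
    dissolution_sand: float

    @property
    def ncc(self) -> float:
        return net_community_calcification(self)


def net_community_calcification(fluxes: AnnualFluxes) -> float:
    """NCC = production − bioerosion − sediment dissolution."""
    return (
        fluxes.production_coral
        + fluxes.production_cca
        - fluxes.erosion_parrotfish
        - fluxes.erosion_urchin
        - fluxes.erosion_sponge
        - fluxes.erosion_micro
        - fluxes.dissolution_sand
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the scenario × adaptation × restoration experiment matrix."""

    label: str
    climate: ClimateSeries
    thermal: ThermalConfig = field(default_factory=ThermalConfig)
    restoration: RestorationSchedule | None = None
    bleaching_enabled: bool = True
    mortality: MortalityTable = field(default_factory=MortalityTable.default)
    restoration_groups: dict[str, dict[str, float]] | None = None
    growth_rate: float = 0.01
    bleaching_growth_rate: float = 0.005


@dataclass(frozen=True)
class BudgetTrajectory:
    """Per-transect annual series of fluxes, NCC and community snapshots."""

    transect_id: str
    years: np.ndarray
    production_coral: np.ndarray
    production_cca: np.ndarray
    erosion_parrotfish: np.ndarray
    erosion_urchin: np.ndarray
    erosion_sponge: np.ndarray
    erosion_micro: np.ndarray
    dissolution_sand: np.ndarray
    ncc: np.ndarray
    state_snapshots: tuple[TransectState, ...]

    def __post_init__(self) -> None:
        recomputed = (
            self.production_coral
            + self.production_cca
            - self.erosion_parrotfish
            - self.erosion_urchin
            - self.erosion_sponge
            - self.erosion_micro
            - self.dissolution_sand
        )
        if not np.allclose(recomputed, self.ncc, atol=1e-6):
            raise InvalidParameterError("ncc inconsistent with flux components")


def step_year(
    state: TransectState,
    thermal_year: ThermalYear,
    spec: ScenarioSpec,
    rates: RateConfig,
    sst: float,
    omega: float,
) -> tuple[TransectState, AnnualFluxes]:
    """Advance one transect by one year; returns the new state and fluxes."""
    severity = thermal_year.severity if spec.bleaching_enabled else Severity.NONE
    if severity is None:
        raise InvalidParameterError("thermal year must carry a classified severity")
    bleaching_year = severity is not Severity.NONE
    state = apply_growth(state, bleaching_year, spec.growth_rate, spec.bleaching_growth_rate)
    if spec.restoration is not None:
        state = apply_restoration(
            state, thermal_year.year, spec.restoration, spec.restoration_groups
        )
    state = apply_bleaching_mortality(state, severity, spec.mortality)
    fluxes = AnnualFluxes(
        production_coral=coral_production(state, rates, sst, omega),
        production_cca=cca_production(state, rates, sst, omega),
        erosion_parrotfish=parrotfish_erosion(state, rates),
        erosion_urchin=urchin_erosion(state, rates),
        erosion_sponge=sponge_erosion(state, rates, sst, omega),
        erosion_micro=micro_erosion(state, rates, sst, omega),
        dissolution_sand=sand_dissolution(state, rates, omega),
    )
    return state, fluxes


def run_projection(
    initial_states: list[TransectState],
    spec: ScenarioSpec,
    rates: RateConfig,
    start_year: int | None = None,
    end_year: int | None = None,
) -> list[BudgetTrajectory]:
    """Iterate ``step_year`` over every transect across the projection window."""
    start = spec.climate.start_year if start_year is None else start_year
    end = spec.climate.end_year if end_year is None else end_year
    if not spec.climate.covers(start, end):
        raise CoverageError(
            f"climate {spec.climate.scenario_label!r} does not cover {start}–{end}"
        )
    thermal_years = {
        ty.year: ty
        for ty in classify_years(annual_max_dhw(spec.climate, spec.thermal), spec.thermal)
    }
    env = spec.climate.annual_means()
    years = np.arange(start, end + 1)
    trajectories = []
    for init in initial_states:
        state = init
        cols: dict[str, list[float]] = {k: [] for k in (
            "production_coral", "production_cca", "erosion_parrotfish", "erosion_urchin",
            "erosion_sponge", "erosion_micro", "dissolution_sand", "ncc",
        )}
        snapshots = []
        for year in years:
            sst = float(env.loc[year, "sst_c"])
            omega = float(env.loc[year, "omega_ar"])
            state, fluxes = step_year(state, thermal_years[year], spec, rates, sst, omega)
            for name in cols:
                cols[name].append(fluxes.ncc if name == "ncc" else getattr(fluxes, name))
            snapshots.append(state)
        trajectories.append(
            BudgetTrajectory(
                transect_id=init.transect_id,
                years=years.copy(),
                state_snapshots=tuple(snapshots),
                **{k: np.array(v) for k, v in cols.items()},
            )
        )
    return trajectories


def mean_trajectory(trajs: list[BudgetTrajectory]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cross-transect mean and sample standard deviation of NCC per year.

    Returns ``(years, mean, sd)``; with a single transect sd is defined
    as zero.
    """
    if not trajs:
        raise InvalidParameterError("no trajectories")
    years = trajs[0].years
    for t in trajs[1:]:
        if not np.array_equal(t.years, years):
            raise InvalidParameterError("trajectories cover different year ranges")
    ncc = np.vstack([t.ncc for t in trajs])
    mean = ncc.mean(axis=0)
    sd = ncc.std(axis=0, ddof=1) if len(trajs) > 1 else np.zeros_like(mean)
    return years, mean, sd


def onset_of_net_erosion(years: np.ndarray, ncc: np.ndarray) -> int | None:
    """First year from which NCC is negative through the end of the series."""
    years = np.asarray(years)
    ncc = np.asarray(ncc)
    if len(years) == 0 or len(years) != len(ncc):
        raise InvalidParameterError("years and ncc must be equal-length and non-empty")
    onset = None
    for year, value in zip(years[::-1], ncc[::-1]):
        if value >= 0:
            break
        onset = int(year)
    return onset
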