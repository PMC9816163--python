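"""Synthetic forcing and census generators for end-to-end testing.

Real applications drive the model with downscaled earth-system-model output
and in-water census surveys. This module generates structurally equivalent
stand-ins: monthly SST with a seasonal sinusoid peaking in August, a
scenario-shaped secular warming trend and iid monthly noise; a declining
Ω_Ar trajectory; and Florida-Keys-inshore-patch-reef-like transects
(~25 % total coral cover dominated by *Orbicella faveolata*, with clionaid
sponge, urchin and parrotfish censuses of realistic magnitude).

Default warming targets echo a high-emission (~3.5 °C by 2100) versus
moderate-mitigation (~1.8 °C) contrast, with end-of-century Ω_Ar near 2.6
and 3.2 respectively. These are package defaults for a plausible forcing
contrast, not calibrated reproductions of any ensemble.

All randomness flows from a single integer seed through spawned numpy
generators, so every generated object is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .budget_engine import ScenarioSpec
from .climate_forcing import ClimateSeries
from .community import ParrotfishRecord, TransectState
from .errors import InvalidParameterError
from .thermal_stress import ThermalConfig

__all__ = [
    "SyntheticClimateSpec",
    "SyntheticReefSpec",
    "ScenarioPair",
    "gen_climate",
    "gen_reef",
    "gen_scenario_pair",
]

DEFAULT_TAXON_MIX = {
    "Orbicella faveolata": 0.55,
    "Orbicella annularis": 0.08,
    "Siderastrea siderea": 0.12,
    "Porites astreoides": 0.10,
    "Montastraea cavernosa": 0.06,
    "Colpophyllia natans": 0.04,
    "Porites porites": 0.03,
    "Diploria labyrinthiformis": 0.02,
}

# Poisson means for parrotfish counts per belt survey, keyed like the
# default bite-rate table.
DEFAULT_PARROTFISH_MEANS = {
    ("Scarus iseri", "initial", "5-14"): 6.0,
    ("Scarus iseri", "terminal", "15-24"): 2.0,
    ("Sparisoma aurofrenatum", "initial", "15-24"): 4.0,
    ("Sparisoma aurofrenatum", "terminal", "25-34"): 1.5,
    ("Sparisoma viride", "initial", "15-24"): 2.0,
    ("Sparisoma viride", "terminal", "25-34"): 0.8,
}


@dataclass(frozen=True)
class SyntheticClimateSpec:
    """Parameters of the synthetic monthly climate generator."""

    start_year: int = 2019
    end_year: int = 2100
    base_sst_mean: float = 26.5
    seasonal_amplitude: float = 4.5  # August peak near 31 °C
    warming_by_2100: float = 3.5
    warming_shape: str = "linear"  # or "stabilizing"
    omega_start: float = 3.9
    omega_by_2100: float = 2.6
    monthly_noise_sd: float = 0.3
    omega_noise_sd: float = 0.02
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise InvalidParameterError("end_year must exceed start_year")
        if self.seasonal_amplitude < 0 or self.monthly_noise_sd < 0 or self.omega_noise_sd < 0:
            raise InvalidParameterError("amplitudes and noise sds must be non-negative")
        if self.warming_shape not in ("linear", "stabilizing"):
            raise InvalidParameterError(f"unknown warming shape {self.warming_shape!r}")


@dataclass(frozen=True)
class SyntheticReefSpec:
    """Parameters of the synthetic transect-census generator."""

    n_transects: int = 6
    total_coral_cover_mean: float = 25.0
    total_coral_cover_sd: float = 5.0
    taxon_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TAXON_MIX))
    rugosity_range: tuple[float, float] = (1.4, 2.1)
    cca_range: tuple[float, float] = (2.0, 6.0)
    sand_range: tuple[float, float] = (15.0, 30.0)
    substrate_range: tuple[float, float] = (25.0, 40.0)
    sponge_area_mean_cm2_m2: float = 250.0
    urchin_count_mean: float = 12.0
    urchin_diameter_mean_cm: float = 3.5
    urchin_diameter_sd_cm: float = 1.0
    parrotfish_means: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PARROTFISH_MEANS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        wsum = sum(self.taxon_mix.values())
        if abs(wsum - 1.0) > 1e-9:
            raise InvalidParameterError(f"taxon mix weights sum to {wsum}, not 1")
        if self.n_transects < 1:
            raise InvalidParameterError("need at least one transect")
        if (
            self.total_coral_cover_mean
            + self.cca_range[0]
            + self.sand_range[0]
            + self.substrate_range[0]
            > 100
        ):
            raise InvalidParameterError("mean coral cover infeasible with minimum other covers")


def _trend_fraction(spec: SyntheticClimateSpec, t: np.ndarray) -> np.ndarray:
    """Warming fraction in [0, ~1] versus normalized time t (0 at start, 1 at 2100)."""
    if spec.warming_shape == "linear":
        return t
    # stabilizing: fast early rise saturating toward 2100, tanh-shaped
    return np.tanh(2.0 * t) / np.tanh(2.0)


def gen_climate(spec: SyntheticClimateSpec) -> ClimateSeries:
    """Monthly SST and Ω_Ar series: trend + seasonal sinusoid + iid noise."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n_years = spec.end_year - spec.start_year + 1
    years = np.repeat(np.arange(spec.start_year, spec.end_year + 1), 12)
    months = np.tile(np.arange(1, 13), n_years)
    # mid-month decimal time, normalized so the warming target is hit at 2100
    t = (years + (months - 0.5) / 12.0 - spec.start_year) / (2100 - spec.start_year)
    trend = spec.warming_by_2100 * _trend_fraction(spec, np.maximum(t, 0.0))
    seasonal = spec.seasonal_amplitude * np.cos(2 * np.pi * (months - 8) / 12.0)
    sst = spec.base_sst_mean + trend + seasonal + rng.normal(0, spec.monthly_noise_sd, len(years))
    omega = (
        spec.omega_start
        + (spec.omega_by_2100 - spec.omega_start) * _trend_fraction(spec, np.maximum(t, 0.0))
        + rng.normal(0, spec.omega_noise_sd, len(years))
    )
    return ClimateSeries(
        scenario_label=spec.label,
        years=years,
        months=months,
        sst=np.clip(sst, -1.9, 44.9),
        omega_ar=np.clip(omega, 0.05, 5.95),
    )


def gen_reef(spec: SyntheticReefSpec) -> list[TransectState]:
    """Generate ``n_transects`` census states with distinct ids."""
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_transects)
    transects = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        total_coral = float(
            np.clip(
                rng.normal(spec.total_coral_cover_mean, spec.total_coral_cover_sd), 5.0, 60.0
            )
        )
        coral = {t: total_coral * w for t, w in spec.taxon_mix.items() if w > 0}
        cca = float(rng.uniform(*spec.cca_range))
        sand = float(rng.uniform(*spec.sand_range))
        substrate = float(rng.uniform(*spec.substrate_range))
        # keep the benthic budget closed: compress sand/substrate if needed
        total = total_coral + cca + sand + substrate
        if total > 95.0:
            scale = (95.0 - total_coral - cca) / (sand + substrate)
            sand *= scale
            substrate *= scale
        rugosity = float(rng.uniform(*spec.rugosity_range))
        sponge_area = float(max(0.0, rng.normal(spec.sponge_area_mean_cm2_m2, 60.0)))
        sponge = {
            "Cliothosa delitrix": 0.6 * sponge_area,
            "Cliona varians": 0.4 * sponge_area,
        }
        n_urchins = int(rng.poisson(spec.urchin_count_mean))
        diameters = tuple(
            float(d)
            for d in np.clip(
                rng.normal(spec.urchin_diameter_mean_cm, spec.urchin_diameter_sd_cm, n_urchins),
                0.5,
                12.0,
            )
        )
        urchins = {"Echinometra": diameters} if diameters else {}
        census = []
        for (species, phase, size_class), lam in spec.parrotfish_means.items():
            count = int(rng.poisson(lam))
            if count > 0:
                census.append(ParrotfishRecord(species, phase, size_class, count))
        transects.append(
            TransectState(
                transect_id=f"T{i + 1}",
                coral_cover=coral,
                cca_cover=cca,
                sand_cover=sand,
                substrate_cover=substrate,
                rugosity=rugosity,
                sponge_cover=sponge,
                urchin_sizes=urchins,
                parrotfish_census=tuple(census),
            )
        )
    return transects


class ScenarioPair(NamedTuple):
    harsh: ScenarioSpec
    mild: ScenarioSpec
    transects: list[TransectState]


def gen_scenario_pair(
    seed: int,
    adaptation_offset: float = 0.0,
    restoration=None,
    bleaching_enabled: bool = True,
    start_year: int = 2019,
    end_year: int = 2100,
) -> ScenarioPair:
    """High-emission vs moderate-mitigation scenario pair sharing one reef.

    The two climates use the same seed (identical noise) and a linear
    warming shape, differing only in end-of-century SST and Ω_Ar targets,
    so the mild forcing is month-by-month no harsher than the harsh one.
    """
    climate_seed, reef_seed = (int(s.generate_state(1)[0] % 2**31) for s in
                               np.random.SeedSequence(seed).spawn(2))
    common = dict(start_year=start_year, end_year=end_year, seed=climate_seed)
    harsh_climate = gen_climate(
        SyntheticClimateSpec(
            warming_by_2100=3.5, omega_by_2100=2.6, label="SSP5-8.5-like", **common
        )
    )
    mild_climate = gen_climate(
        SyntheticClimateSpec(
            warming_by_2100=1.8, omega_by_2100=3.2, label="SSP2-4.5-like", **common
        )
    )
    transects = gen_reef(SyntheticReefSpec(seed=reef_seed))
    thermal = ThermalConfig(adaptation_offset=adaptation_offset)
    mk = lambda climate: ScenarioSpec(
        label=climate.scenario_label,
        climate=climate,
        thermal=thermal,
        restoration=restoration,
        bleaching_enabled=bleaching_enabled,
    )
    return ScenarioPair(harsh=mk(harsh_climate), mild=mk(mild_climate), transects=transects)
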