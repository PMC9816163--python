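"""Carbonate fluxes from community state and environment.

Census-based carbonate budgeting (ReefBudget-style): gross production by
corals and crustose coralline algae, and four bioerosion components —
macroboring sponges, parrotfish, urchins, microborers — plus chemical
dissolution of sediment. All fluxes are kg CaCO₃ per planar m² of reef per
year, returned as positive magnitudes; the budget equation applies signs.

Covers are recorded along the reef contour, so cover-based fluxes (coral,
CCA, microborers) multiply by transect rugosity to express them per planar
m². Parrotfish and urchin belts are planar surveys and are not
rugosity-scaled; grazing is also treated as environment-independent
(mechanical erosion insensitive to warming/acidification).

Environmental modification of rates uses additive linear response curves:
``multiplier = max(floor, 1 + a·ΔT + b·ΔΩ)`` relative to a reference
environment, with temperature and saturation-state contributions combined by
addition (a deliberately non-synergistic interaction). CCA additionally
collapses to zero below a hard Ω_Ar threshold. The shipped default curves
are package defaults calibrated only to reproduce the *direction* of
late-century contribution changes (coral calcification down, macro- and
microborers up, grazing flat, CCA collapse under high-emission forcing);
users fitting site-specific curves should replace them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

from .community import TransectState
from .errors import ConfigurationError, InvalidParameterError

__all__ = [
    "ResponseCurve",
    "RateConfig",
    "response_multiplier",
    "coral_production",
    "cca_production",
    "sponge_erosion",
    "parrotfish_erosion",
    "urchin_erosion",
    "micro_erosion",
    "sand_dissolution",
    "load_coral_rates",
    "load_parrotfish_rates",
]

# Reference environment at which base rates apply: contemporary annual-mean
# SST (°C) and Ω_Ar at a Florida-Keys inshore patch reef.
DEFAULT_REFERENCE_ENV = (26.5, 3.9)


@dataclass(frozen=True)
class ResponseCurve:
    """Additive linear sensitivity of a rate to SST and Ω_Ar.

    ``temp_slope`` is the relative rate change per °C above ``sst_ref``;
    ``omega_slope`` the relative change per unit Ω_Ar above ``omega_ref``
    (positive slope ⇒ rate falls as Ω_Ar falls). The multiplier is floored
    at ``floor`` and forced to zero below ``collapse_omega`` when set.
    """

    name: str
    temp_slope: float = 0.0
    omega_slope: float = 0.0
    sst_ref: float = DEFAULT_REFERENCE_ENV[0]
    omega_ref: float = DEFAULT_REFERENCE_ENV[1]
    floor: float = 0.0
    collapse_omega: float | None = None

    def __post_init__(self) -> None:
        if self.floor < 0:
            raise InvalidParameterError("floor must be non-negative")


def response_multiplier(curve: ResponseCurve, sst: float, omega: float) -> float:
    """Dimensionless rate multiplier at the given environment.

    Exactly 1 at the reference environment; temperature and Ω contributions
    combine by addition, never multiplication.
    """
    if curve.collapse_omega is not None and omega < curve.collapse_omega:
        return 0.0
    raw = 1.0 + curve.temp_slope * (sst - curve.sst_ref) + curve.omega_slope * (omega - curve.omega_ref)
    return max(curve.floor, raw)


def _default_curves() -> dict[str, ResponseCurve]:
    return {
        # calcifiers slow with warming and falling Ω_Ar
        "coral": ResponseCurve("coral", temp_slope=-0.05, omega_slope=0.10),
        # CCA: highly OA-sensitive, collapses entirely at low Ω_Ar
        "cca": ResponseCurve("cca", temp_slope=-0.02, omega_slope=0.75, collapse_omega=2.0),
        # chemically mediated borers accelerate under acidification
        "macroborer": ResponseCurve("macroborer", temp_slope=0.05, omega_slope=-0.60),
        "microborer": ResponseCurve("microborer", temp_slope=0.08, omega_slope=-1.00),
    }


def load_coral_rates() -> dict[str, float]:
    """Species calcification rates (kg CaCO₃ m⁻² of living cover yr⁻¹)."""
    with resources.files("reefcast.data").joinpath("coral_calcification_rates.csv").open() as fh:
        return {row["taxon"]: float(row["rate_kg_m2_yr"]) for row in csv.DictReader(fh)}


def load_parrotfish_rates() -> dict[tuple[str, str, str], float]:
    """Bite-driven erosion (kg fish⁻¹ yr⁻¹) by (species, phase, size class)."""
    with resources.files("reefcast.data").joinpath("parrotfish_bite_rates.csv").open() as fh:
        return {
            (row["species"], row["phase"], row["size_class"]): float(row["erosion_kg_fish_yr"])
            for row in csv.DictReader(fh)
        }


@dataclass(frozen=True)
class RateConfig:
    """All biological rate parameters and response curves.

    Erosion rates are stored as positive magnitudes. ``urchin_rate_params``
    maps taxon → (a, b) of the allometric per-individual rate
    ``a · d^b`` kg yr⁻¹ for test diameter d (cm). ``sand_dissolution_slope``
    is kg m⁻² yr⁻¹ of additional dissolution per unit Ω_Ar below the
    reference (plus a constant ``sand_dissolution_baseline`` at reference).
    """

    coral_calcification: dict[str, float] = field(default_factory=load_coral_rates)
    cca_calcification: float = 0.5
    sponge_erosion_rates: dict[str, float] = field(
        default_factory=lambda: {
            "Cliothosa delitrix": 7.7,
            "Cliona caribbaea": 6.0,
            "Cliona tenuis": 6.5,
            "Cliona varians": 2.1,
        }
    )
    parrotfish_bite: dict[tuple[str, str, str], float] = field(
        default_factory=load_parrotfish_rates
    )
    urchin_rate_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"Diadema": (0.0029, 1.6959), "Echinometra": (0.0007, 1.7)}
    )
    micro_erosion_rate: float = 0.240
    sand_dissolution_slope: float = 0.10
    sand_dissolution_baseline: float = 0.0
    reference_env: tuple[float, float] = DEFAULT_REFERENCE_ENV
    parrotfish_survey_area_m2: float = 120.0  # 4 m x 30 m belt
    urchin_survey_area_m2: float = 20.0  # 2 m x 10 m belt
    curves: dict[str, ResponseCurve] = field(default_factory=_default_curves)
    coral_fallback_rate: float | None = None

    def __post_init__(self) -> None:
        for name, value in (
            ("cca_calcification", self.cca_calcification),
            ("micro_erosion_rate", self.micro_erosion_rate),
            ("sand_dissolution_slope", self.sand_dissolution_slope),
            ("sand_dissolution_baseline", self.sand_dissolution_baseline),
        ):
            if value < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        for table_name, table in (
            ("coral_calcification", self.coral_calcification),
            ("sponge_erosion_rates", self.sponge_erosion_rates),
            ("parrotfish_bite", self.parrotfish_bite),
        ):
            if any(v < 0 for v in table.values()):
                raise InvalidParameterError(f"negative rate in {table_name}")
        if self.parrotfish_survey_area_m2 <= 0 or self.urchin_survey_area_m2 <= 0:
            raise InvalidParameterError("survey areas must be positive")

    def curve(self, group: str) -> ResponseCurve:
        try:
            return self.curves[group]
        except KeyError:
            raise ConfigurationError(f"no response curve configured for group {group!r}") from None

    def coral_rate(self, taxon: str) -> float:
        if taxon in self.coral_calcification:
            return self.coral_calcification[taxon]
        if self.coral_fallback_rate is not None:
            return self.coral_fallback_rate
        raise ConfigurationError(f"no calcification rate for taxon {taxon!r} and no fallback")

    def urchin_rate(self, taxon: str, diameter_cm: float) -> float:
        if diameter_cm <= 0:
            raise InvalidParameterError("urchin test diameter must be positive")
        try:
            a, b = self.urchin_rate_params[taxon]
        except KeyError:
            raise ConfigurationError(f"no urchin erosion parameters for {taxon!r}") from None
        return a * diameter_cm**b


def coral_production(
    state: TransectState, cfg: RateConfig, sst: float, omega: float
) -> float:
    """Gross coral calcification, kg CaCO₃ per planar m² per year."""
    mult = response_multiplier(cfg.curve("coral"), sst, omega)
    return sum(
        (cov / 100.0) * state.rugosity * cfg.coral_rate(taxon) * mult
        for taxon, cov in state.coral_cover.items()
    )


def cca_production(state: TransectState, cfg: RateConfig, sst: float, omega: float) -> float:
    """Gross CCA calcification, kg m⁻² yr⁻¹ (zero below the collapse Ω_Ar)."""
    mult = response_multiplier(cfg.curve("cca"), sst, omega)
    return (state.cca_cover / 100.0) * state.rugosity * cfg.cca_calcification * mult


def sponge_erosion(state: TransectState, cfg: RateConfig, sst: float, omega: float) -> float:
    """Macroboring-sponge erosion, kg m⁻² yr⁻¹ (positive magnitude).

    Sponge tissue area is censused in cm² per m² of transect; 10⁴ cm² m⁻²
    corresponds to full cover at the species' per-m²-of-tissue rate.
    """
    mult = response_multiplier(cfg.curve("macroborer"), sst, omega)
    total = 0.0
    for species, area_cm2 in state.sponge_cover.items():
        if species not in cfg.sponge_erosion_rates:
            raise ConfigurationError(f"no erosion rate for sponge {species!r}")
        total += (area_cm2 / 1e4) * cfg.sponge_erosion_rates[species] * mult
    return total


def parrotfish_erosion(state: TransectState, cfg: RateConfig) -> float:
    """Parrotfish grazing erosion, kg m⁻² yr⁻¹; environment-independent."""
    total = 0.0
    for rec in state.parrotfish_census:
        key = (rec.species, rec.phase, rec.size_class)
        if key not in cfg.parrotfish_bite:
            raise ConfigurationError(f"no bite rate for parrotfish class {key!r}")
        total += rec.count * cfg.parrotfish_bite[key]
    return total / cfg.parrotfish_survey_area_m2


def urchin_erosion(state: TransectState, cfg: RateConfig) -> float:
    """Urchin erosion from test-size frequencies, kg m⁻² yr⁻¹."""
    total = 0.0
    for taxon, sizes in state.urchin_sizes.items():
        for d in sizes:
            total += cfg.urchin_rate(taxon, d)
    return total / cfg.urchin_survey_area_m2


def micro_erosion(state: TransectState, cfg: RateConfig, sst: float, omega: float) -> float:
    """Microborer erosion of available substrate, kg m⁻² yr⁻¹."""
    mult = response_multiplier(cfg.curve("microborer"), sst, omega)
    return (state.substrate_cover / 100.0) * state.rugosity * cfg.micro_erosion_rate * mult


def sand_dissolution(state: TransectState, cfg: RateConfig, omega: float) -> float:
    """Chemical dissolution of sediment, kg m⁻² yr⁻¹.

    The per-unit-sand rate g(Ω) is non-increasing in Ω_Ar: baseline at the
    reference saturation state plus a linear increase as Ω_Ar falls below it.
    """
    _, omega_ref = cfg.reference_env
    g = cfg.sand_dissolution_baseline + cfg.sand_dissolution_slope * max(0.0, omega_ref - omega)
    return (state.sand_cover / 100.0) * g
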