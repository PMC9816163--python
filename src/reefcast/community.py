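"""Benthic community state and its year-to-year dynamics.

A :class:`TransectState` is a full census of one permanent transect: percent
cover by coral taxon, crustose coralline algae (CCA), sand and available
(dead framework) substrate, transect rugosity, plus the bioeroder censuses
(clionaid sponge tissue area, urchin test-size lists, parrotfish counts by
species/phase/size class).

Three processes evolve the state annually:

* baseline growth — each coral taxon's cover grows by a relative rate
  (1 %/yr by default, halved to 0.5 % in bleaching years);
* bleaching mortality — severe bleaching removes a species-specific
  fraction of cover per year (field-derived loss rates for the eight main
  Cheeca-Rocks species); modest bleaching removes one third of that,
  the MB rates being derived from the ASB rates by ``derive_modest_loss``;
* restoration planting — scheduled absolute percentage-point additions per
  taxon group, spread evenly over each planting phase.

Mortality and growth are multiplicative on existing cover, so cover decays
toward (but never reaches) zero. Cover lost to mortality becomes available
substrate; planted cover draws substrate (then sand) down, keeping the
benthic budget closed at ≤ 100 %.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

from .errors import ConfigurationError, InvalidParameterError
from .thermal_stress import Severity

__all__ = [
    "ParrotfishRecord",
    "TransectState",
    "MortalityTable",
    "RestorationSchedule",
    "derive_modest_loss",
    "apply_growth",
    "apply_bleaching_mortality",
    "build_restoration_schedule",
    "apply_restoration",
    "DEFAULT_RESTORATION_GROUPS",
    "DEFAULT_PHASE_TARGETS",
    "DEFAULT_PHASE_STARTS",
]

logger = logging.getLogger(__name__)

COVER_TOL = 1e-9


class ParrotfishRecord(NamedTuple):
    species: str
    phase: str
    size_class: str
    count: int


@dataclass(frozen=True)
class TransectState:
    """Benthic census of one transect at one time point.

    Covers are percent of the transect (recorded along the reef contour);
    ``rugosity`` (contour/planar length, ≥ 1) converts them to planar-area
    fluxes downstream. ``sponge_cover`` is cm² of live sponge tissue per m²
    of transect; ``urchin_sizes`` lists test diameters (cm) per taxon;
    ``parrotfish_census`` counts fish per belt-survey area.
    """

    transect_id: str
    coral_cover: dict[str, float]
    cca_cover: float
    sand_cover: float
    substrate_cover: float
    rugosity: float
    sponge_cover: dict[str, float] = field(default_factory=dict)
    urchin_sizes: dict[str, tuple[float, ...]] = field(default_factory=dict)
    parrotfish_census: tuple[ParrotfishRecord, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "urchin_sizes",
            {k: tuple(v) for k, v in self.urchin_sizes.items()},
        )
        object.__setattr__(
            self,
            "parrotfish_census",
            tuple(ParrotfishRecord(*r) for r in self.parrotfish_census),
        )
        for taxon, cov in self.coral_cover.items():
            if cov < 0:
                raise InvalidParameterError(f"negative cover for {taxon!r}")
        for name, cov in (
            ("cca_cover", self.cca_cover),
            ("sand_cover", self.sand_cover),
            ("substrate_cover", self.substrate_cover),
        ):
            if cov < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.total_cover > 100 + COVER_TOL:
            raise InvalidParameterError(
                f"coral+CCA+sand+substrate = {self.total_cover:.3f}% exceeds 100%"
            )
        if self.rugosity < 1:
            raise InvalidParameterError("rugosity must be >= 1")
        for taxon, sizes in self.urchin_sizes.items():
            if any(d <= 0 for d in sizes):
                raise InvalidParameterError(f"non-positive urchin test diameter for {taxon!r}")
        for rec in self.parrotfish_census:
            if rec.count <= 0:
                raise InvalidParameterError("parrotfish counts must be positive")
        for sp, area in self.sponge_cover.items():
            if area < 0:
                raise InvalidParameterError(f"negative sponge area for {sp!r}")

    @property
    def total_coral_cover(self) -> float:
        return sum(self.coral_cover.values())

    @property
    def total_cover(self) -> float:
        return self.total_coral_cover + self.cca_cover + self.sand_cover + self.substrate_cover


def derive_modest_loss(asb_loss_percent: float) -> float:
    """Modest-bleaching loss rate (%) as one third of the severe rate.

    Rounded half-up to one decimal place, the convention that reproduces
    the published modest-bleaching column from the severe one.
    """
    if not 0 <= asb_loss_percent <= 100:
        raise InvalidParameterError("ASB loss percent must be in [0, 100]")
    third = Decimal(str(asb_loss_percent)) / Decimal(3)
    return float(third.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# Annual relative cover-loss rates (fractions) under severe bleaching for the
# eight main species at the study site, from repeat photomosaic surveys over
# two consecutive bleaching years.
_ASB_LOSS_PERCENT = {
    "Orbicella faveolata": 6.8,
    "Orbicella annularis": 4.5,
    "Siderastrea siderea": 1.7,
    "Porites astreoides": 11.0,
    "Porites porites": 11.0,
    "Colpophyllia natans": 7.1,
    "Montastraea cavernosa": 12.5,
}


@dataclass(frozen=True)
class MortalityTable:
    """Relative annual cover-loss fractions under severe / modest bleaching.

    ``fallback`` controls taxa without an entry: ``"cover_weighted_mean"``
    (default) uses the cover-weighted mean loss of tabulated taxa present in
    the state; ``None`` raises a configuration error.
    """

    asb_loss: dict[str, float]
    mb_loss: dict[str, float]
    fallback: str | None = "cover_weighted_mean"

    def __post_init__(self) -> None:
        for table in (self.asb_loss, self.mb_loss):
            for taxon, loss in table.items():
                if not 0 <= loss <= 1:
                    raise InvalidParameterError(f"loss fraction for {taxon!r} outside [0, 1]")
        if self.fallback not in (None, "cover_weighted_mean"):
            raise InvalidParameterError(f"unknown fallback {self.fallback!r}")

    @classmethod
    def default(cls) -> "MortalityTable":
        asb = {t: p / 100.0 for t, p in _ASB_LOSS_PERCENT.items()}
        mb = {t: derive_modest_loss(p) / 100.0 for t, p in _ASB_LOSS_PERCENT.items()}
        return cls(asb_loss=asb, mb_loss=mb)

    def loss_for(self, taxon: str, severity: Severity, state: TransectState) -> float:
        table = self.asb_loss if severity is Severity.SEVERE else self.mb_loss
        if taxon in table:
            return table[taxon]
        if self.fallback is None:
            raise ConfigurationError(f"no bleaching loss rate for taxon {taxon!r} and no fallback")
        known = [(t, c) for t, c in state.coral_cover.items() if t in table]
        total = sum(c for _, c in known)
        if total <= 0:
            # no tabulated cover to weight by; fall back to unweighted mean
            return sum(table.values()) / len(table)
        return sum(table[t] * c for t, c in known) / total


def apply_growth(
    state: TransectState,
    bleaching_year: bool,
    growth_rate: float = 0.01,
    bleaching_growth_rate: float = 0.005,
) -> TransectState:
    """Multiply every coral taxon's cover by ``1 + g``.

    ``g`` is the baseline growth rate (default 1 %/yr) or the reduced
    bleaching-year rate (default 0.5 %/yr). If the benthic total would
    exceed 100 %, coral covers are clamped back proportionally.
    """
    for name, r in (("growth_rate", growth_rate), ("bleaching_growth_rate", bleaching_growth_rate)):
        if not 0 <= r <= 1:
            raise InvalidParameterError(f"{name} must be in [0, 1]")
    g = bleaching_growth_rate if bleaching_year else growth_rate
    coral = {t: c * (1 + g) for t, c in state.coral_cover.items()}
    total = sum(coral.values()) + state.cca_cover + state.sand_cover + state.substrate_cover
    if total > 100:
        coral_total = sum(coral.values())
        scale = (coral_total - (total - 100)) / coral_total
        coral = {t: c * scale for t, c in coral.items()}
    new = dataclasses.replace(state, coral_cover=coral)
    if new.total_cover > 100 + COVER_TOL:  # pragma: no cover - defensive
        raise ReefcastInternalError("cover budget violated after growth clamping")
    return new


class ReefcastInternalError(RuntimeError):
    pass


def apply_bleaching_mortality(
    state: TransectState,
    severity: Severity,
    table: MortalityTable,
    transfer_to_substrate: bool = True,
) -> TransectState:
    """Remove a severity-dependent fraction of each coral taxon's cover.

    Loss is proportional to existing cover, so cover decays geometrically
    and never reaches zero. Lost cover is credited to available substrate
    (dead framework open to microborers) unless ``transfer_to_substrate``
    is disabled.
    """
    if severity is Severity.NONE:
        return state
    coral = {}
    lost = 0.0
    for taxon, cov in state.coral_cover.items():
        loss = table.loss_for(taxon, severity, state)
        coral[taxon] = cov * (1 - loss)
        lost += cov * loss
    substrate = state.substrate_cover + (lost if transfer_to_substrate else 0.0)
    return dataclasses.replace(state, coral_cover=coral, substrate_cover=substrate)


@dataclass(frozen=True)
class RestorationSchedule:
    """Absolute percentage-point cover additions: year → taxon group → pp."""

    additions: dict[int, dict[str, float]]

    def __post_init__(self) -> None:
        for year, groups in self.additions.items():
            for group, pp in groups.items():
                if pp < 0:
                    raise InvalidParameterError(f"negative addition for {group!r} in {year}")

    def total_added(self) -> float:
        return sum(pp for groups in self.additions.values() for pp in groups.values())

    def group_totals(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for groups in self.additions.values():
            for group, pp in groups.items():
                totals[group] = totals.get(group, 0.0) + pp
        return totals


# Published planting targets for the patch-reef habitat: absolute percent
# cover increases per taxon group and phase. Phase 1 totals 2.80 %, phase 2
# totals 6.20 %, 9 % combined over two 10-year phases.
DEFAULT_PHASE_TARGETS: dict[int, dict[str, float]] = {
    1: {"Orbicella": 1.65, "Brain": 1.15},
    2: {"Orbicella": 3.35, "Brain": 2.35, "Other small stony": 0.50},
}
DEFAULT_PHASE_STARTS: dict[int, int] = {1: 2022, 2: 2032}

DEFAULT_RESTORATION_GROUPS: dict[str, dict[str, float]] = {
    "Orbicella": {"Orbicella faveolata": 0.5, "Orbicella annularis": 0.5},
    "Brain": {"Diploria labyrinthiformis": 0.5, "Colpophyllia natans": 0.5},
    "Other small stony": {"Siderastrea siderea": 0.5, "Porites astreoides": 0.5},
}


def build_restoration_schedule(
    phase_targets: dict[int, dict[str, float]] | None = None,
    phase_starts: dict[int, int] | None = None,
    phase_duration_years: int = 10,
) -> RestorationSchedule:
    """Spread each phase's group targets into equal annual additions.

    Each phase target (absolute percentage points) is divided evenly over
    ``phase_duration_years`` consecutive planting years starting at that
    phase's start year. Overlapping phases sum.
    """
    if phase_targets is None:
        phase_targets = DEFAULT_PHASE_TARGETS
    if phase_starts is None:
        phase_starts = DEFAULT_PHASE_STARTS
    if phase_duration_years < 1:
        raise InvalidParameterError("phase duration must be >= 1 year")
    additions: dict[int, dict[str, float]] = {}
    for phase, targets in phase_targets.items():
        if phase not in phase_starts:
            raise InvalidParameterError(f"no start year for phase {phase!r}")
        start = phase_starts[phase]
        for group, target in targets.items():
            if target < 0:
                raise InvalidParameterError(f"negative target for {group!r}")
            if target == 0:
                continue
            annual = target / phase_duration_years
            for year in range(start, start + phase_duration_years):
                additions.setdefault(year, {})
                additions[year][group] = additions[year].get(group, 0.0) + annual
    return RestorationSchedule(additions=additions)


def apply_restoration(
    state: TransectState,
    year: int,
    schedule: RestorationSchedule,
    group_to_taxa: dict[str, dict[str, float]] | None = None,
) -> TransectState:
    """Add this year's scheduled cover, drawing down substrate then sand.

    Group additions are split across constituent taxa by weights summing to
    one. If free substrate + sand cannot absorb the full addition, the
    addition is truncated to what fits and a warning is logged.
    """
    if group_to_taxa is None:
        group_to_taxa = DEFAULT_RESTORATION_GROUPS
    groups = schedule.additions.get(year)
    if not groups:
        return state
    requested = 0.0
    per_taxon: dict[str, float] = {}
    for group, pp in groups.items():
        if group not in group_to_taxa:
            raise ConfigurationError(f"restoration group {group!r} has no taxon mapping")
        weights = group_to_taxa[group]
        wsum = sum(weights.values())
        if abs(wsum - 1.0) > 1e-9:
            raise ConfigurationError(f"weights for group {group!r} sum to {wsum}, not 1")
        for taxon, w in weights.items():
            per_taxon[taxon] = per_taxon.get(taxon, 0.0) + pp * w
        requested += pp
    available = state.substrate_cover + state.sand_cover
    if requested > available:
        logger.warning(
            "transect %s year %d: restoration addition %.3f pp truncated to %.3f pp "
            "(benthos full)",
            state.transect_id,
            year,
            requested,
            available,
        )
        scale = available / requested if requested > 0 else 0.0
        per_taxon = {t: pp * scale for t, pp in per_taxon.items()}
        requested = available
    from_substrate = min(requested, state.substrate_cover)
    from_sand = requested - from_substrate
    coral = dict(state.coral_cover)
    for taxon, pp in per_taxon.items():
        coral[taxon] = coral.get(taxon, 0.0) + pp
    return dataclasses.replace(
        state,
        coral_cover=coral,
        substrate_cover=state.substrate_cover - from_substrate,
        sand_cover=state.sand_cover - from_sand,
    )
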