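"""Experiment configuration, orchestration, and tabular output.

An experiment is a matrix of scenario cells — climate forcing × adaptation
offset × restoration on/off × bleaching on/off — described in a YAML config.
``run_experiment`` runs every cell through the budget engine, converts the
budgets to accretion diagnostics, and writes per-cell trajectory CSVs, a
summary CSV (onset years, end-of-century NCC, keep-pace horizons) and a JSON
run manifest. Outputs are written via write-then-rename so a failed run
never leaves truncated files, and are byte-reproducible for a given config
and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accretion import AccretionConfig, accumulated_height, keep_pace_horizon, rap_max, sediment_infill
from .budget_engine import BudgetTrajectory, ScenarioSpec, mean_trajectory, onset_of_net_erosion, run_projection
from .climate_forcing import ClimateSeries, SlrSeries, build_slr_series, read_climate_csv
from .community import build_restoration_schedule
from .errors import ConfigurationError
from .rates import RateConfig
from .synthetic_data import SyntheticClimateSpec, SyntheticReefSpec, gen_climate, gen_reef
from .thermal_stress import ThermalConfig, annual_max_dhw, asb_onset_year, classify_years

__all__ = ["ExperimentConfig", "load_config", "run_experiment"]

logger = logging.getLogger(__name__)

_TOP_KEYS = {
    "seed", "out_dir", "start_year", "end_year", "adaptation_offsets",
    "restoration", "bleaching", "climates", "reef", "slr", "thermal", "accretion",
}
_CLIMATE_KEYS = {
    "label", "path", "warming_by_2100", "omega_by_2100", "warming_shape",
    "base_sst_mean", "seasonal_amplitude", "omega_start", "monthly_noise_sd",
}
_REEF_KEYS = {
    "n_transects", "total_coral_cover_mean", "total_coral_cover_sd",
    "rugosity_range", "sponge_area_mean_cm2_m2", "urchin_count_mean",
}
_SLR_KEYS = {"label", "rate_cm_per_decade", "path"}
_THERMAL_KEYS = {"bleaching_threshold", "weeks_per_month", "asb_dhw", "mb_dhw"}
_ACCRETION_KEYS = {
    "carbonate_density", "framework_porosity",
    "parrotfish_sediment_reincorporation", "other_bioeroder_sediment_reincorporation",
}


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully validated experiment description with defaults applied."""

    seed: int = 0
    out_dir: str = "reefcast_out"
    start_year: int = 2019
    end_year: int = 2100
    adaptation_offsets: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0)
    restoration: tuple[bool, ...] = (False, True)
    bleaching: tuple[bool, ...] = (True,)
    climates: tuple[dict, ...] = (
        {"label": "SSP5-8.5-like", "warming_by_2100": 3.5, "omega_by_2100": 2.6},
        {"label": "SSP2-4.5-like", "warming_by_2100": 1.8, "omega_by_2100": 3.2},
    )
    reef: dict = field(default_factory=dict)
    slr: tuple[dict, ...] = (
        {"label": "HR-CESM-like", "rate_cm_per_decade": 3.1},
        {"label": "LR-CESM-like", "rate_cm_per_decade": 4.4},
    )
    thermal: dict = field(default_factory=dict)
    accretion: dict = field(default_factory=dict)
    source_text: str = ""

    def __post_init__(self) -> None:
        if not self.adaptation_offsets or not self.climates:
            raise ConfigurationError("the scenario matrix must be non-empty")
        labels = [c.get("label") for c in self.climates]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("climate labels must be unique")


def load_config(path: str | os.PathLike) -> ExperimentConfig:
    """Load and validate a YAML experiment config; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config root")
    for i, climate in enumerate(raw.get("climates", [])):
        _check_keys(climate, _CLIMATE_KEYS, f"climates[{i}]")
        if "label" not in climate:
            raise ConfigurationError(f"climates[{i}] needs a label")
        if "path" in climate and not Path(climate["path"]).exists():
            raise FileNotFoundError(f"climate file not found: {climate['path']}")
    _check_keys(raw.get("reef", {}), _REEF_KEYS, "reef")
    for i, entry in enumerate(raw.get("slr", [])):
        _check_keys(entry, _SLR_KEYS, f"slr[{i}]")
    _check_keys(raw.get("thermal", {}), _THERMAL_KEYS, "thermal")
    _check_keys(raw.get("accretion", {}), _ACCRETION_KEYS, "accretion")
    kwargs: dict = {k: raw[k] for k in raw}
    for key in ("adaptation_offsets", "restoration", "bleaching", "climates", "slr"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    try:
        return ExperimentConfig(source_text=text, **kwargs)
    except TypeError as exc:  # wrong value shapes
        raise ConfigurationError(f"config schema violation: {exc}") from None


def _atomic_write(path: Path, writer) -> None:
    tmp = path.with_name(path.name + ".tmp")
    writer(tmp)
    os.replace(tmp, path)


def _cell_label(climate_label: str, offset: float, restored: bool, bleaching: bool) -> str:
    parts = [climate_label.replace(" ", "_"), f"adapt{offset:g}"]
    parts.append("restored" if restored else "unrestored")
    if not bleaching:
        parts.append("nobleach")
    return "_".join(parts)


def _build_climates(cfg: ExperimentConfig, seed: int) -> list[ClimateSeries]:
    series = []
    for entry in cfg.climates:
        if "path" in entry:
            series.append(read_climate_csv(entry["path"], entry["label"]))
        else:
            params = {k: v for k, v in entry.items() if k not in ("label", "path")}
            series.append(
                gen_climate(
                    SyntheticClimateSpec(
                        start_year=cfg.start_year,
                        end_year=cfg.end_year,
                        seed=seed,
                        label=entry["label"],
                        **params,
                    )
                )
            )
    return series


def _build_slr(cfg: ExperimentConfig) -> list[SlrSeries]:
    return [
        build_slr_series(
            entry["rate_cm_per_decade"], cfg.start_year, cfg.end_year, entry.get("label", "")
        )
        for entry in cfg.slr
    ]


def _trajectory_frame(
    trajs: list[BudgetTrajectory], acfg: AccretionConfig, slr: SlrSeries | None
) -> pd.DataFrame:
    rows = []
    for traj in trajs:
        infill = np.array(
            [
                sediment_infill(p, u, s, acfg)
                for p, u, s in zip(traj.erosion_parrotfish, traj.erosion_urchin, traj.erosion_sponge)
            ]
        )
        rap = np.array([rap_max(n, i, acfg) for n, i in zip(traj.ncc, infill)])
        height = accumulated_height(rap)
        frame = pd.DataFrame(
            {
                "year": traj.years,
                "transect_id": traj.transect_id,
                "production_coral": traj.production_coral,
                "production_cca": traj.production_cca,
                "erosion_parrotfish": traj.erosion_parrotfish,
                "erosion_urchin": traj.erosion_urchin,
                "erosion_sponge": traj.erosion_sponge,
                "erosion_micro": traj.erosion_micro,
                "dissolution_sand": traj.dissolution_sand,
                "ncc": traj.ncc,
                "rap_mm_yr": rap,
                "accumulated_height_mm": height,
            }
        )
        if slr is not None:
            rise_mm = np.array(
                [(slr.rise_at(int(y)) - slr.rise_at(int(traj.years[0]))) * 10.0 for y in traj.years]
            )
            frame["slr_mm"] = rise_mm
            frame["keeping_pace"] = height >= rise_mm
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run the full scenario matrix and write the result bundle to disk.

    Returns the summary table (one row per matrix cell) that is also
    written to ``summary.csv``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(2)
    climate_seed, reef_seed = (int(s.generate_state(1)[0] % 2**31) for s in seeds)
    climates = _build_climates(cfg, climate_seed)
    slr_series = _build_slr(cfg)
    transects = gen_reef(SyntheticReefSpec(seed=reef_seed, **cfg.reef))
    rates = RateConfig()
    acfg = AccretionConfig(**cfg.accretion)
    schedule = build_restoration_schedule()
    summary_rows = []
    for climate in climates:
        for offset in cfg.adaptation_offsets:
            thermal = ThermalConfig(adaptation_offset=float(offset), **cfg.thermal)
            asb = asb_onset_year(classify_years(annual_max_dhw(climate, thermal), thermal))
            for restored in cfg.restoration:
                for bleaching in cfg.bleaching:
                    spec = ScenarioSpec(
                        label=_cell_label(climate.scenario_label, offset, restored, bleaching),
                        climate=climate,
                        thermal=thermal,
                        restoration=schedule if restored else None,
                        bleaching_enabled=bool(bleaching),
                    )
                    trajs = run_projection(transects, spec, rates, cfg.start_year, cfg.end_year)
                    years, mean_ncc, sd_ncc = mean_trajectory(trajs)
                    frame = _trajectory_frame(trajs, acfg, slr_series[0] if slr_series else None)
                    _atomic_write(
                        out_dir / f"trajectories_{spec.label}.csv",
                        lambda p, frame=frame: frame.to_csv(p, index=False),
                    )
                    mean_rap = (
                        frame.groupby("year")["rap_mm_yr"].mean().reindex(years).to_numpy()
                    )
                    row = {
                        "scenario": climate.scenario_label,
                        "adaptation_offset": float(offset),
                        "restored": bool(restored),
                        "bleaching_enabled": bool(bleaching),
                        "asb_onset_year": asb,
                        "erosion_onset_year": onset_of_net_erosion(years, mean_ncc),
                        "ncc_2100_mean": float(mean_ncc[-1]),
                        "ncc_2100_sd": float(sd_ncc[-1]),
                        "rap_start_mean_mm_yr": float(mean_rap[0]),
                    }
                    for slr in slr_series:
                        row[f"keep_pace_{slr.label}"] = keep_pace_horizon(years, mean_rap, slr)
                    summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    _atomic_write(out_dir / "summary.csv", lambda p: summary.to_csv(p, index=False))
    manifest = {
        "seed": cfg.seed,
        "reefcast_version": __version__,
        "config_sha256": hashlib.sha256(cfg.source_text.encode()).hexdigest(),
        "n_cells": len(summary_rows),
        "n_transects": len(transects),
    }
    _atomic_write(
        out_dir / "manifest.json",
        lambda p: Path(p).write_text(json.dumps(manifest, indent=2) + "\n"),
    )
    logger.info("wrote %d matrix cells to %s", len(summary_rows), out_dir)
    return summary
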