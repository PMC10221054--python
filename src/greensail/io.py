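"""Run configuration, table/JSON writers and logging setup.

A run configuration is a YAML file mirroring
:class:`~greensail.experiments.ScenarioConfig`: it names either
component spectra CSV files or built-in synthetic profiles, the scenario
grids, the sun/view geometry (defaulting to 30 deg solar zenith, nadir
view, fully direct irradiance) and the vegetation-index bands.
Everything is validated up front with field-path error messages.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd
import pydantic
import yaml

from .experiments import (
    PAI_GRID,
    PROPORTION_GRID,
    ForestType,
    RegressionFit,
    ScenarioConfig,
    SIM_COLUMNS,
)
from .sail import Geometry
from .spectra import (
    BARK_BROADLEAF,
    BARK_CONIFER,
    BROADLEAF_SPECIES,
    CANONICAL_GRID,
    NEEDLELEAF_SPECIES,
    SOIL_DEFAULT,
    SPECIES_PROFILES,
    ComponentKind,
    ComponentOptics,
    average_optics,
    generate_component_optics,
    read_optics_csv,
    resample,
)
from .vegindex import VIConfig

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_sim_table",
    "read_sim_table",
    "write_fit",
    "configure_logging",
]

logger = logging.getLogger("greensail")


class RunConfig(pydantic.BaseModel):
    """Validated run configuration (YAML-serialisable)."""

    model_config = pydantic.ConfigDict(extra="forbid", frozen=True)

    forest_type: Literal["DBF", "ENF"] = "DBF"
    # spectra: either CSV paths or a synthetic profile name per component
    leaf_csv: Optional[str] = None
    branch_csv: Optional[str] = None
    soil_csv: Optional[str] = None
    leaf_profile: Optional[str] = None      # species name or "mean"
    seed: int = 0

    pai_values: tuple[float, ...] = PAI_GRID
    green_proportions: tuple[float, ...] = PROPORTION_GRID

    solar_zenith_deg: float = 30.0
    view_zenith_deg: float = 0.0
    relative_azimuth_deg: float = 0.0
    direct_fraction: float = 1.0

    arrangement: Literal["blocks", "interleaved"] = "blocks"
    n_pairs: int = 10

    blue_band: tuple[float, float] = (459.0, 479.0)
    red_band: tuple[float, float] = (620.0, 670.0)
    nir_band: tuple[float, float] = (841.0, 876.0)
    savi_L: float = 0.5

    output_dir: str = "."
    log_level: str = "INFO"

    @pydantic.field_validator("solar_zenith_deg", "view_zenith_deg")
    @classmethod
    def _zenith_range(cls, v: float) -> float:
        if not 0.0 <= v < 90.0:
            raise ValueError("zenith angle must be in [0, 90) degrees")
        return v

    @pydantic.field_validator("direct_fraction")
    @classmethod
    def _fraction_range(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("direct_fraction must be in [0, 1]")
        return v

    @pydantic.field_validator("pai_values")
    @classmethod
    def _pai_positive(cls, v):
        if not v or any(p <= 0 for p in v):
            raise ValueError("pai_values must be a non-empty positive sequence")
        return v

    @pydantic.field_validator("green_proportions")
    @classmethod
    def _proportion_range(cls, v):
        if not v or any(not 0 < p <= 1 for p in v):
            raise ValueError("green_proportions must lie in (0, 1]")
        return v

    @pydantic.field_validator("leaf_csv", "branch_csv", "soil_csv")
    @classmethod
    def _file_exists(cls, v):
        if v is not None and not Path(v).is_file():
            raise ValueError(f"file not found: {v}")
        return v

    @pydantic.field_validator("leaf_profile")
    @classmethod
    def _known_profile(cls, v):
        if v is not None and v != "mean" and v not in SPECIES_PROFILES:
            raise ValueError(
                f"unknown leaf profile {v!r}; known: "
                f"{['mean', *sorted(SPECIES_PROFILES)]}"
            )
        return v

    # ---- assembly ------------------------------------------------------

    def _leaf_optics(self) -> ComponentOptics:
        if self.leaf_csv is not None:
            return resample(
                read_optics_csv(self.leaf_csv, ComponentKind.LEAF), CANONICAL_GRID
            )
        profile = self.leaf_profile or "mean"
        if profile == "mean":
            names = (BROADLEAF_SPECIES if self.forest_type == "DBF"
                     else NEEDLELEAF_SPECIES)
            leaves = [
                generate_component_optics(
                    ComponentKind.LEAF, SPECIES_PROFILES[n], seed=self.seed
                )
                for n in names
            ]
            return average_optics(
                leaves, label=f"{self.forest_type.lower()}-mean-leaf"
            )
        return generate_component_optics(
            ComponentKind.LEAF, SPECIES_PROFILES[profile], seed=self.seed
        )

    def _branch_optics(self) -> ComponentOptics:
        if self.branch_csv is not None:
            return resample(
                read_optics_csv(self.branch_csv, ComponentKind.BRANCH),
                CANONICAL_GRID,
            )
        bark = BARK_BROADLEAF if self.forest_type == "DBF" else BARK_CONIFER
        return generate_component_optics(ComponentKind.BRANCH, bark, seed=self.seed)

    def _soil_optics(self) -> ComponentOptics:
        if self.soil_csv is not None:
            return resample(
                read_optics_csv(self.soil_csv, ComponentKind.SOIL), CANONICAL_GRID
            )
        return generate_component_optics(ComponentKind.SOIL, SOIL_DEFAULT,
                                         seed=self.seed)

    def to_scenario_config(self) -> ScenarioConfig:
        """Build the in-memory scenario configuration (reads any CSVs)."""
        return ScenarioConfig(
            forest_type=ForestType(self.forest_type),
            leaf_optics=self._leaf_optics(),
            branch_optics=self._branch_optics(),
            soil_optics=self._soil_optics(),
            pai_values=self.pai_values,
            green_proportions=self.green_proportions,
            geometry=Geometry(
                solar_zenith_deg=self.solar_zenith_deg,
                view_zenith_deg=self.view_zenith_deg,
                relative_azimuth_deg=self.relative_azimuth_deg,
                direct_fraction=self.direct_fraction,
            ),
            arrangement=self.arrangement,
            n_pairs=self.n_pairs,
            vi_config=VIConfig(
                blue_band=self.blue_band,
                red_band=self.red_band,
                nir_band=self.nir_band,
                savi_L=self.savi_L,
            ),
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a YAML mapping")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips with load_config)."""
    data = cfg.model_dump(mode="json")
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def write_sim_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a simulation table as CSV, fixed column order, 6 sig. digits."""
    cols = [c for c in SIM_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False, float_format="%.6g")


def read_sim_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fit(fit: RegressionFit, path: str | Path) -> None:
    """Write a regression fit as JSON with exactly its dataclass fields."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(fit), fh, indent=2, sort_keys=True)
        fh.write("\n")


def configure_logging(level: str = "INFO") -> None:
    """Send package logs to stderr at the requested level."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())
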