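"""Simulation grids, FPAR-vegetation-index correlations and inversion fits.

Drives the layered SAIL solver over grids of plant area index (PAI) and
green-component proportion for two forest classes (deciduous broadleaf,
DBF; evergreen coniferous, ENF), computes vegetation indices from the
simulated nadir reflectance, correlates them with the partitioned FPAR,
and fits the linear green-FPAR ~ VI inversion models.

Standard grid: PAI in {0.1, 0.5, 1, 2, 3, 4, 5, 6, 7} crossed with green
proportions {0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.98}; sun at 30 deg zenith,
nadir view, fully direct illumination.  Inversion scenarios hold the
woody area constant at 0.5 (DBF) or the green proportion at 90% (ENF)
while PAI runs over the integers 1..7.
"""
from __future__ import annotations

import dataclasses
import enum
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .fpar import FparResult, partition_canopy_fpar
from .sail import CanopyLayer, CanopyStack, Geometry, SailError, solve_stack
from .spectra import (
    BARK_BROADLEAF,
    BARK_CONIFER,
    BROADLEAF_SPECIES,
    NEEDLELEAF_SPECIES,
    SOIL_DEFAULT,
    SPECIES_PROFILES,
    ComponentKind,
    ComponentOptics,
    SpectralCurve,
    average_optics,
    generate_component_optics,
)
from .vegindex import VIConfig, indices_from_spectrum

__all__ = [
    "ForestType",
    "ScenarioConfig",
    "RegressionFit",
    "PAI_GRID",
    "PROPORTION_GRID",
    "INVERSION_PAI_GRID",
    "build_stack",
    "default_scenario_config",
    "run_scenario_grid",
    "run_inversion_scenario",
    "pearson_r",
    "correlation_table",
    "fit_green_fpar_vi",
    "species_fpar_table",
    "SIM_COLUMNS",
]

logger = logging.getLogger("greensail")

#: Standard plant-area-index grid.
PAI_GRID: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0)
#: Standard green-component proportion grid.
PROPORTION_GRID: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.98)
#: PAI values for the inversion scenarios.
INVERSION_PAI_GRID: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0)

SIM_COLUMNS: tuple[str, ...] = (
    "forest_type", "pai", "green_proportion",
    "fpar_total", "fpar_pav", "fpar_npv",
    "ndvi", "evi", "evi2", "savi",
    "r_blue", "r_red", "r_nir",
)


class ForestType(str, enum.Enum):
    DBF = "DBF"
    ENF = "ENF"


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to run one simulation grid."""

    forest_type: ForestType
    leaf_optics: ComponentOptics
    branch_optics: ComponentOptics
    soil_optics: ComponentOptics
    pai_values: tuple[float, ...] = PAI_GRID
    green_proportions: tuple[float, ...] = PROPORTION_GRID
    geometry: Geometry = Geometry()
    arrangement: str = "blocks"
    n_pairs: int = 10
    vi_config: VIConfig = VIConfig()

    def __post_init__(self) -> None:
        object.__setattr__(self, "forest_type", ForestType(self.forest_type))
        object.__setattr__(self, "pai_values", tuple(float(p) for p in self.pai_values))
        object.__setattr__(
            self, "green_proportions",
            tuple(float(p) for p in self.green_proportions),
        )
        if any(p <= 0 for p in self.pai_values):
            raise SailError("pai_values must be positive")
        if any(not 0 < p <= 1 for p in self.green_proportions):
            raise SailError("green proportions must lie in (0, 1]")
        if self.arrangement not in ("interleaved", "blocks"):
            raise SailError("arrangement must be 'interleaved' or 'blocks'")
        if self.n_pairs < 1:
            raise SailError("n_pairs must be >= 1")


def default_scenario_config(forest_type: ForestType | str, seed: int = 0,
                            **overrides) -> ScenarioConfig:
    """Standard configuration with synthetic forest-type mean spectra.

    Leaf optics are the mean of the built-in broadleaf (DBF) or
    needleleaf (ENF) species profiles; branch optics use the matching
    bark profile; the soil is the default dry-soil ramp.
    """
    forest_type = ForestType(forest_type)
    if forest_type is ForestType.DBF:
        species, bark = BROADLEAF_SPECIES, BARK_BROADLEAF
    else:
        species, bark = NEEDLELEAF_SPECIES, BARK_CONIFER
    leaves = [
        generate_component_optics(ComponentKind.LEAF, SPECIES_PROFILES[name],
                                  seed=seed)
        for name in species
    ]
    leaf = average_optics(leaves, label=f"{forest_type.value.lower()}-mean-leaf")
    branch = generate_component_optics(ComponentKind.BRANCH, bark, seed=seed)
    soil = generate_component_optics(ComponentKind.SOIL, SOIL_DEFAULT, seed=seed)
    return ScenarioConfig(
        forest_type=forest_type,
        leaf_optics=leaf,
        branch_optics=branch,
        soil_optics=soil,
        **overrides,
    )


def build_stack(pai: float, green_proportion: float,
                leaf_optics: ComponentOptics, branch_optics: ComponentOptics,
                soil_optics: ComponentOptics,
                arrangement: str = "blocks",
                n_pairs: int = 10) -> CanopyStack:
    """Assemble a canopy stack with the given area budget.

    ``interleaved``: n_pairs alternating (leaf, branch) sublayers, each
    carrying an equal share of its component's area — a layered stand-in
    for a well-mixed canopy.  ``blocks``: one leaf layer above one
    branch layer.  Zero-area layers are not emitted.
    """
    if pai <= 0:
        raise SailError("pai must be positive")
    if not 0 < green_proportion <= 1:
        raise SailError("green_proportion must lie in (0, 1]")
    leaf_area = pai * green_proportion
    branch_area = pai - leaf_area
    layers: list[CanopyLayer] = []
    if arrangement == "interleaved":
        for _ in range(n_pairs):
            if leaf_area > 0:
                layers.append(CanopyLayer(leaf_optics, leaf_area / n_pairs))
            if branch_area > 0:
                layers.append(CanopyLayer(branch_optics, branch_area / n_pairs))
    elif arrangement == "blocks":
        if leaf_area > 0:
            layers.append(CanopyLayer(leaf_optics, leaf_area))
        if branch_area > 0:
            layers.append(CanopyLayer(branch_optics, branch_area))
    else:
        raise SailError("arrangement must be 'interleaved' or 'blocks'")
    return CanopyStack(layers=tuple(layers), soil=soil_optics)


def _simulate_row(cfg: ScenarioConfig, pai: float, proportion: float) -> dict:
    stack = build_stack(
        pai, proportion, cfg.leaf_optics, cfg.branch_optics, cfg.soil_optics,
        cfg.arrangement, cfg.n_pairs,
    )
    try:
        profile = solve_stack(stack, cfg.geometry)
    except SailError as exc:
        raise SailError(
            f"scenario {cfg.forest_type.value} pai={pai} "
            f"proportion={proportion}: {exc}"
        ) from exc
    result: FparResult = partition_canopy_fpar(profile, stack)
    refl = SpectralCurve(profile.wavelengths_nm, profile.reflectance_factor)
    bands, vis = indices_from_spectrum(refl, cfg.vi_config)
    return {
        "forest_type": cfg.forest_type.value,
        "pai": pai,
        "green_proportion": proportion,
        "fpar_total": result.fpar_total,
        "fpar_pav": result.fpar_pav,
        "fpar_npv": result.fpar_npv,
        "ndvi": vis.ndvi,
        "evi": vis.evi,
        "evi2": vis.evi2,
        "savi": vis.savi,
        "r_blue": bands.r_blue,
        "r_red": bands.r_red,
        "r_nir": bands.r_nir,
    }


def run_scenario_grid(cfg: ScenarioConfig) -> pd.DataFrame:
    """One row per (PAI, green proportion); deterministic given inputs."""
    rows = []
    for pai in cfg.pai_values:
        for proportion in cfg.green_proportions:
            logger.debug(
                "simulating %s pai=%.2f proportion=%.2f",
                cfg.forest_type.value, pai, proportion,
            )
            rows.append(_simulate_row(cfg, pai, proportion))
    return pd.DataFrame(rows, columns=SIM_COLUMNS)


def run_inversion_scenario(cfg: ScenarioConfig,
                           npv_area_index: float = 0.5,
                           enf_green_proportion: float = 0.9,
                           pai_values: Sequence[float] = INVERSION_PAI_GRID
                           ) -> pd.DataFrame:
    """Seasonal-structure scenarios used for the inversion fit.

    DBF: the woody area index is a year-round constant
    (``npv_area_index``); the leaf area is PAI minus that constant.
    ENF: the green proportion is a year-round constant
    (``enf_green_proportion``).
    """
    rows = []
    for pai in pai_values:
        if cfg.forest_type is ForestType.DBF:
            if pai <= npv_area_index:
                raise SailError(
                    f"PAI {pai} must exceed the fixed woody area index "
                    f"{npv_area_index}"
                )
            proportion = (pai - npv_area_index) / pai
        else:
            proportion = enf_green_proportion
        rows.append(_simulate_row(cfg, float(pai), float(proportion)))
    return pd.DataFrame(rows, columns=SIM_COLUMNS)


def pearson_r(xs: Iterable[float], ys: Iterable[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(list(xs), dtype=float)
    y = np.asarray(list(ys), dtype=float)
    if x.size != y.size:
        raise SailError("pearson_r requires equal-length sequences")
    if x.size < 3:
        raise SailError("pearson_r requires at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise SailError("pearson_r undefined for a constant sequence")
    return float(scipy.stats.pearsonr(x, y).statistic)


def correlation_table(simtable: pd.DataFrame,
                      fpar_columns: Sequence[str] = ("fpar_total", "fpar_pav",
                                                     "fpar_npv"),
                      vi_columns: Sequence[str] = ("ndvi", "evi", "evi2",
                                                   "savi"),
                      by: str | None = None) -> pd.DataFrame:
    """Pearson correlations for every (FPAR column, VI column) pair.

    With ``by`` set (e.g. ``"green_proportion"``) correlations are
    stratified per group and the group value becomes an index level.
    """
    if by is not None:
        parts = []
        for value, group in simtable.groupby(by, sort=True):
            part = correlation_table(group, fpar_columns, vi_columns)
            part.insert(0, by, value)
            parts.append(part)
        out = pd.concat(parts, ignore_index=False)
        return out.set_index(by, append=True).reorder_levels([1, 0])
    data = {
        vi: [pearson_r(simtable[f], simtable[vi]) for f in fpar_columns]
        for vi in vi_columns
    }
    return pd.DataFrame(data, index=list(fpar_columns))


@dataclasses.dataclass(frozen=True)
class RegressionFit:
    """A linear green-FPAR ~ VI inversion model and its error metrics.

    ``mean_error`` is the mean absolute residual on the fitted rows;
    ``error_rate_percent`` normalises it by the mean simulated green
    FPAR.
    """

    vi_name: str
    slope: float
    intercept: float
    pearson_r: float
    mean_error: float
    error_rate_percent: float

    def __post_init__(self) -> None:
        if abs(self.pearson_r) > 1 + 1e-12:
            raise SailError("|pearson_r| must be <= 1")
        if self.mean_error < 0:
            raise SailError("mean_error must be >= 0")

    def predict(self, vi: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(vi) + self.intercept


def fit_green_fpar_vi(simtable: pd.DataFrame, vi_name: str) -> RegressionFit:
    """Ordinary least squares of green FPAR on one vegetation index."""
    if vi_name not in simtable.columns:
        raise SailError(f"unknown vegetation index column {vi_name!r}")
    if len(simtable) < 3:
        raise SailError("need at least 3 rows to fit")
    x = simtable[vi_name].to_numpy(dtype=float)
    y = simtable["fpar_pav"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise SailError(f"degenerate design: {vi_name} is constant")
    res = scipy.stats.linregress(x, y)
    predicted = res.slope * x + res.intercept
    mean_error = float(np.mean(np.abs(predicted - y)))
    mean_true = float(np.mean(y))
    if mean_true <= 0:
        raise SailError("mean simulated green FPAR is not positive")
    return RegressionFit(
        vi_name=vi_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        mean_error=mean_error,
        error_rate_percent=100.0 * mean_error / mean_true,
    )


def species_fpar_table(species_optics: Sequence[ComponentOptics],
                       branch_optics: ComponentOptics,
                       soil_optics: ComponentOptics,
                       pai_values: Sequence[float] = (1.0, 4.0, 7.0),
                       proportions: Sequence[float] = (0.98, 0.5),
                       geometry: Geometry = Geometry(),
                       arrangement: str = "blocks",
                       n_pairs: int = 10) -> pd.DataFrame:
    """Green FPAR per species across a small scenario table.

    Rows are species (labelled by the optics), columns a MultiIndex of
    (green proportion, PAI).
    """
    columns = pd.MultiIndex.from_product(
        [list(proportions), list(pai_values)], names=["proportion", "pai"]
    )
    rows = {}
    for optics in species_optics:
        values = []
        for proportion in proportions:
            for pai in pai_values:
                stack = build_stack(pai, proportion, optics, branch_optics,
                                    soil_optics, arrangement, n_pairs)
                profile = solve_stack(stack, geometry)
                values.append(partition_canopy_fpar(profile, stack).fpar_pav)
        rows[optics.label] = values
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
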