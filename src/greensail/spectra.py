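"""Component optical-property spectra.

Containers for reflectance/transmittance curves of canopy components
(green leaves, woody elements, soil background), CSV readers/writers,
linear resampling, PAR absorptance, and a deterministic synthetic-spectra
generator used when measured spectra are not available.

All curves live on a wavelength grid in nanometres.  The canonical grid
used throughout the package is 400-1000 nm at 5 nm resolution (121
samples): it covers the photosynthetically active region (400-700 nm)
and every vegetation-index band.
"""
from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_GRID",
    "PAR_BAND",
    "ComponentKind",
    "SpectralCurve",
    "ComponentOptics",
    "SpectraError",
    "LeafProfile",
    "RampProfile",
    "SPECIES_PROFILES",
    "BROADLEAF_SPECIES",
    "NEEDLELEAF_SPECIES",
    "BARK_BROADLEAF",
    "BARK_CONIFER",
    "SOIL_DEFAULT",
    "read_optics_csv",
    "write_optics_csv",
    "resample",
    "generate_component_optics",
    "average_optics",
    "par_absorptance",
]

#: Canonical wavelength grid: 400-1000 nm at 5 nm (121 samples).
CANONICAL_GRID: np.ndarray = np.arange(400.0, 1000.0 + 1e-9, 5.0)

#: Photosynthetically active radiation window (nm).
PAR_BAND: tuple[float, float] = (400.0, 700.0)


class SpectraError(ValueError):
    """Invalid spectral data (grid, range or energy-balance violation)."""


class ComponentKind(str, enum.Enum):
    """Canopy component class.

    Leaves scatter in reflection and transmission; woody elements
    (branches, stems) and soil reflect but do not transmit.
    """

    LEAF = "leaf"
    BRANCH = "branch"
    SOIL = "soil"


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SpectralCurve:
    """A sampled spectral quantity on a strictly increasing nm grid."""

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or v.ndim != 1 or wl.size != v.size:
            raise SpectraError(
                f"wavelengths and values must be 1-D of equal length, "
                f"got {wl.shape} vs {v.shape}"
            )
        if wl.size == 0:
            raise SpectraError("empty spectral curve")
        if not np.all(np.diff(wl) > 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(v))):
            raise SpectraError("non-finite entries in spectral curve")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def require_unit_interval(self, name: str = "curve") -> "SpectralCurve":
        """Validate that all values lie in [0, 1] (fractional quantity)."""
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            bad = int(np.argmax((self.values < 0) | (self.values > 1)))
            raise SpectraError(
                f"{name} outside [0, 1] at {self.wavelengths_nm[bad]:.1f} nm: "
                f"{self.values[bad]:.4f}"
            )
        return self

    def interp(self, grid: Sequence[float]) -> "SpectralCurve":
        """Linear interpolation onto ``grid``; extrapolation is refused."""
        g = np.asarray(grid, dtype=float)
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if g.min() < lo - 1e-9 or g.max() > hi + 1e-9:
            raise SpectraError(
                f"requested grid [{g.min():.1f}, {g.max():.1f}] nm outside "
                f"source range [{lo:.1f}, {hi:.1f}] nm"
            )
        return SpectralCurve(g, np.interp(g, self.wavelengths_nm, self.values))

    def band_mask(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        return (self.wavelengths_nm >= lo - 1e-9) & (self.wavelengths_nm <= hi + 1e-9)


@dataclasses.dataclass(frozen=True)
class ComponentOptics:
    """Reflectance and transmittance of one canopy component.

    Invariants: both curves share one grid, each value is a fraction,
    rho+tau <= 1 everywhere, and non-leaf components have zero
    transmittance (woody elements and soil absorb whatever they do not
    reflect).
    """

    kind: ComponentKind
    label: str
    reflectance: SpectralCurve
    transmittance: SpectralCurve

    def __post_init__(self) -> None:
        kind = ComponentKind(self.kind)
        object.__setattr__(self, "kind", kind)
        r, t = self.reflectance, self.transmittance
        if not np.array_equal(r.wavelengths_nm, t.wavelengths_nm):
            raise SpectraError("reflectance and transmittance grids differ")
        r.require_unit_interval("reflectance")
        t.require_unit_interval("transmittance")
        total = r.values + t.values
        if np.any(total > 1 + 1e-9):
            bad = int(np.argmax(total))
            raise SpectraError(
                f"reflectance+transmittance > 1 at "
                f"{r.wavelengths_nm[bad]:.1f} nm: {total[bad]:.4f}"
            )
        if kind is not ComponentKind.LEAF and np.any(t.values != 0.0):
            raise SpectraError(f"{kind.value} component must have zero transmittance")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.reflectance.wavelengths_nm

    @property
    def single_scattering_albedo(self) -> np.ndarray:
        return self.reflectance.values + self.transmittance.values


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("wavelength_nm", "reflectance")


def read_optics_csv(path: str | Path, kind: ComponentKind | str,
                    label: str | None = None) -> ComponentOptics:
    """Read a component spectrum from CSV.

    Expected header columns: ``wavelength_nm``, ``reflectance`` and,
    for leaves, ``transmittance`` (optional for branch/soil, where a
    missing column means zero transmission).  Rows are sorted by
    wavelength before validation.
    """
    kind = ComponentKind(kind)
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise SpectraError(f"{path}: missing column(s) {missing}")
    if "transmittance" not in df.columns:
        if kind is ComponentKind.LEAF:
            raise SpectraError(f"{path}: leaf spectra require a transmittance column")
        df = df.assign(transmittance=0.0)
    df = df.sort_values("wavelength_nm").reset_index(drop=True)
    for col in ("wavelength_nm", "reflectance", "transmittance"):
        bad = df.index[~np.isfinite(df[col].to_numpy(dtype=float))]
        if len(bad):
            raise SpectraError(f"{path}: non-numeric {col} at data row {bad[0]}")
    rho = df["reflectance"].to_numpy(dtype=float)
    tau = df["transmittance"].to_numpy(dtype=float)
    for name, col in (("reflectance", rho), ("transmittance", tau)):
        bad = np.flatnonzero((col < 0) | (col > 1))
        if bad.size:
            raise SpectraError(
                f"{path}: {name} outside [0,1] at data row {bad[0]} "
                f"(wavelength {df['wavelength_nm'][bad[0]]})"
            )
    bad = np.flatnonzero(rho + tau > 1 + 1e-9)
    if bad.size:
        raise SpectraError(
            f"{path}: reflectance+transmittance > 1 at data row {bad[0]} "
            f"(wavelength {df['wavelength_nm'][bad[0]]})"
        )
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    return ComponentOptics(
        kind=kind,
        label=label if label is not None else path.stem,
        reflectance=SpectralCurve(wl, rho),
        transmittance=SpectralCurve(wl, tau),
    )


def write_optics_csv(optics: ComponentOptics, path: str | Path) -> None:
    """Write a component spectrum to CSV (full float precision)."""
    df = pd.DataFrame(
        {
            "wavelength_nm": optics.wavelengths_nm,
            "reflectance": optics.reflectance.values,
            "transmittance": optics.transmittance.values,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def resample(optics: ComponentOptics, grid: Sequence[float]) -> ComponentOptics:
    """Linearly resample a component spectrum onto ``grid`` (no extrapolation)."""
    return ComponentOptics(
        kind=optics.kind,
        label=optics.label,
        reflectance=optics.reflectance.interp(grid),
        transmittance=optics.transmittance.interp(grid),
    )


def average_optics(components: Sequence[ComponentOptics], label: str) -> ComponentOptics:
    """Average several component spectra sharing one grid (e.g. forest-type mean)."""
    if not components:
        raise SpectraError("nothing to average")
    wl = components[0].wavelengths_nm
    for c in components[1:]:
        if not np.array_equal(c.wavelengths_nm, wl):
            raise SpectraError("cannot average spectra on different grids")
    kinds = {c.kind for c in components}
    if len(kinds) != 1:
        raise SpectraError("cannot average across component kinds")
    rho = np.mean([c.reflectance.values for c in components], axis=0)
    tau = np.mean([c.transmittance.values for c in components], axis=0)
    return ComponentOptics(
        kind=components[0].kind,
        label=label,
        reflectance=SpectralCurve(wl, rho),
        transmittance=SpectralCurve(wl, tau),
    )


# ---------------------------------------------------------------------------
# PAR absorptance
# ---------------------------------------------------------------------------

def par_absorptance(optics: ComponentOptics,
                    weighting: SpectralCurve | None = None) -> float:
    """Mean absorptance 1-rho-tau over 400-700 nm.

    Uniform weighting by default; an irradiance spectrum may be supplied
    (it is interpolated onto the component grid and renormalised within
    the PAR window).
    """
    wl = optics.wavelengths_nm
    if wl[0] > PAR_BAND[0] + 1e-9 or wl[-1] < PAR_BAND[1] - 1e-9:
        raise SpectraError(
            f"grid [{wl[0]:.0f}, {wl[-1]:.0f}] nm does not cover PAR 400-700 nm"
        )
    mask = (wl >= PAR_BAND[0] - 1e-9) & (wl <= PAR_BAND[1] + 1e-9)
    absorptance = 1.0 - optics.single_scattering_albedo[mask]
    if weighting is None:
        return float(np.mean(absorptance))
    w = np.interp(wl[mask], weighting.wavelengths_nm, weighting.values)
    if np.sum(w) <= 0:
        raise SpectraError("weighting integrates to zero over PAR")
    return float(np.sum(absorptance * w) / np.sum(w))


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class LeafProfile:
    """Shape parameters of a synthetic green-leaf spectrum.

    The leaf is modelled through its single-scattering albedo
    ``omega = rho + tau``: a near-transparent NIR plateau, a logistic red
    edge, and a visible absorption shape built from a baseline plus two
    Gaussian pigment wells (blue ~450 nm, red ~670 nm).  The visible
    absorption is rescaled so the mean 400-700 nm absorptance equals
    ``par_absorptance`` exactly.
    """

    name: str
    par_absorptance: float          # target mean absorptance over 400-700 nm
    nir_albedo: float = 0.93        # rho+tau plateau in the NIR
    red_edge_nm: float = 715.0      # logistic transition centre
    red_edge_width_nm: float = 10.0
    well_blue: float = 0.45         # relative depth of the ~450 nm pigment well
    well_red: float = 0.40          # relative depth of the ~670 nm pigment well
    vis_baseline: float = 0.55      # relative flat visible absorption
    wiggle_amplitude: float = 0.004  # seeded smooth perturbation of the shape

    def __post_init__(self) -> None:
        if not 0.0 < self.par_absorptance < 1.0:
            raise SpectraError("par_absorptance target must be in (0, 1)")
        if not 0.0 < self.nir_albedo < 1.0:
            raise SpectraError("nir_albedo must be in (0, 1)")
        if self.par_absorptance <= 1.0 - self.nir_albedo:
            raise SpectraError(
                "PAR absorptance target must exceed the NIR absorptance floor"
            )


@dataclasses.dataclass(frozen=True)
class RampProfile:
    """Shape parameters of a synthetic non-transmitting spectrum (bark, soil).

    Reflectance is a gentle linear ramp in wavelength with a seeded
    smooth perturbation; transmittance is identically zero.  The ramp
    level is shifted so the mean 400-700 nm absorptance equals
    ``par_absorptance`` exactly.
    """

    name: str
    par_absorptance: float
    slope_per_600nm: float = 0.10   # reflectance rise from 400 to 1000 nm
    wiggle_amplitude: float = 0.004

    def __post_init__(self) -> None:
        if not 0.0 < self.par_absorptance < 1.0:
            raise SpectraError("par_absorptance target must be in (0, 1)")


#: Built-in leaf profiles.  PAR-absorptance targets are realistic
#: laboratory leaf values ordered oak > alder > {spruce, aspen, hemlock}
#: > juniper; broadleaf species carry a brighter NIR plateau than conifers.
SPECIES_PROFILES: Mapping[str, LeafProfile] = {
    "oak": LeafProfile("oak", par_absorptance=0.900, nir_albedo=0.94),
    "alder": LeafProfile("alder", par_absorptance=0.885, nir_albedo=0.93),
    "aspen": LeafProfile("aspen", par_absorptance=0.875, nir_albedo=0.93),
    "spruce": LeafProfile("spruce", par_absorptance=0.876, nir_albedo=0.89,
                          red_edge_nm=710.0),
    "hemlock": LeafProfile("hemlock", par_absorptance=0.874, nir_albedo=0.90,
                           red_edge_nm=710.0),
    "juniper": LeafProfile("juniper", par_absorptance=0.855, nir_albedo=0.88,
                           red_edge_nm=710.0),
}

BROADLEAF_SPECIES: tuple[str, ...] = ("alder", "oak", "aspen")
NEEDLELEAF_SPECIES: tuple[str, ...] = ("hemlock", "juniper", "spruce")

#: Bark reflects ~0.25-0.30 in the visible with a mild upward ramp.
BARK_BROADLEAF = RampProfile("bark-broadleaf", par_absorptance=0.72)
BARK_CONIFER = RampProfile("bark-conifer", par_absorptance=0.75)

#: Bright-ish dry soil: 0.05 at 400 nm ramping to 0.25 at 1000 nm.
SOIL_DEFAULT = RampProfile("soil", par_absorptance=0.90, slope_per_600nm=0.20)


def _seeded_wiggle(grid: np.ndarray, amplitude: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean-ish perturbation: three random long-period sinusoids."""
    x = (grid - grid[0]) / (grid[-1] - grid[0] + 1e-12)
    out = np.zeros_like(grid)
    for _ in range(3):
        period = rng.uniform(0.25, 1.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += rng.uniform(0.3, 1.0) * np.sin(2.0 * np.pi * x / period + phase)
    peak = np.max(np.abs(out))
    return amplitude * out / peak if peak > 0 else out


def _generate_leaf(profile: LeafProfile, grid: np.ndarray,
                   rng: np.random.Generator) -> ComponentOptics:
    lam = grid
    # logistic red edge: ~1 in the visible, ->0 on the NIR plateau
    edge = 1.0 / (1.0 + np.exp((lam - profile.red_edge_nm) / profile.red_edge_width_nm))
    shape = (
        profile.vis_baseline
        + profile.well_blue * np.exp(-((lam - 450.0) / 45.0) ** 2)
        + profile.well_red * np.exp(-((lam - 670.0) / 28.0) ** 2)
    )
    shape = shape * (1.0 + _seeded_wiggle(lam, profile.wiggle_amplitude, rng))
    shape = np.clip(shape, 0.0, None) * edge

    par = (lam >= PAR_BAND[0] - 1e-9) & (lam <= PAR_BAND[1] + 1e-9)
    if not par.any():
        raise SpectraError("grid does not intersect the PAR window")
    alpha_nir = 1.0 - profile.nir_albedo
    if not np.any(shape[par] > 0):
        raise SpectraError("degenerate visible absorption shape")

    # saturating absorption: alpha = 1 - (1 - alpha_nir) exp(-S shape)
    # stays below 1 for any scale S; S is solved so the PAR mean hits the
    # target exactly (monotone in S, hence monotone in the target)
    def mean_alpha(scale: float) -> float:
        return float(np.mean(1.0 - (1.0 - alpha_nir)
                             * np.exp(-scale * shape[par])))

    from scipy.optimize import brentq

    s_hi = 500.0
    if not mean_alpha(0.0) < profile.par_absorptance < mean_alpha(s_hi):
        raise SpectraError(
            f"profile {profile.name!r} PAR-absorptance target "
            f"{profile.par_absorptance} is unreachable on this grid "
            f"(range {mean_alpha(0.0):.3f}..{mean_alpha(s_hi):.3f})"
        )
    scale = brentq(lambda s: mean_alpha(s) - profile.par_absorptance,
                   0.0, s_hi, xtol=1e-12)
    omega = (1.0 - alpha_nir) * np.exp(-scale * shape)
    # leaves reflect slightly more than they transmit in the visible
    refl_fraction = 0.5 + 0.05 * edge
    rho = omega * refl_fraction
    tau = omega - rho
    return ComponentOptics(
        kind=ComponentKind.LEAF,
        label=profile.name,
        reflectance=SpectralCurve(lam, rho),
        transmittance=SpectralCurve(lam, tau),
    )


def _generate_ramp(kind: ComponentKind, profile: RampProfile, grid: np.ndarray,
                   rng: np.random.Generator) -> ComponentOptics:
    lam = grid
    ramp = profile.slope_per_600nm * (lam - 400.0) / 600.0
    ramp = ramp * (1.0 + _seeded_wiggle(lam, profile.wiggle_amplitude, rng))
    par = (lam >= PAR_BAND[0] - 1e-9) & (lam <= PAR_BAND[1] + 1e-9)
    if not par.any():
        raise SpectraError("grid does not intersect the PAR window")
    # shift so mean PAR reflectance hits 1 - target absorptance
    level = (1.0 - profile.par_absorptance) - float(np.mean(ramp[par]))
    rho = level + ramp
    if np.any(rho < 0.0) or np.any(rho > 1.0):
        raise SpectraError(
            f"profile {profile.name!r} targets push reflectance outside [0, 1]"
        )
    zero = np.zeros_like(lam)
    return ComponentOptics(
        kind=kind,
        label=profile.name,
        reflectance=SpectralCurve(lam, rho),
        transmittance=SpectralCurve(lam, zero),
    )


def generate_component_optics(kind: ComponentKind | str,
                              profile: LeafProfile | RampProfile,
                              grid: Sequence[float] | None = None,
                              seed: int = 0) -> ComponentOptics:
    """Generate a deterministic synthetic component spectrum.

    ``seed`` controls only a small smooth perturbation of the spectral
    shape; the mean PAR absorptance is recalibrated to the profile
    target after perturbing, so it is seed-independent.
    """
    kind = ComponentKind(kind)
    lam = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    if not np.all(np.diff(lam) > 0):
        raise SpectraError("grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    if kind is ComponentKind.LEAF:
        if not isinstance(profile, LeafProfile):
            raise SpectraError("leaf generation requires a LeafProfile")
        return _generate_leaf(profile, lam, rng)
    if not isinstance(profile, RampProfile):
        raise SpectraError(f"{kind.value} generation requires a RampProfile")
    return _generate_ramp(kind, profile, lam, rng)
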