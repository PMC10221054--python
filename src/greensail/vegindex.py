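"""Spectral vegetation indices from simulated canopy reflectance.

Band reflectances are unweighted means of the reflectance spectrum over
MODIS-like windows (blue 459-479 nm, red 620-670 nm, NIR 841-876 nm);
from them NDVI, EVI, EVI2 and SAVI are computed:

    NDVI = (N - R) / (N + R)
    EVI  = 2.5 (N - R) / (N + 6 R - 7.5 B + 1)
    EVI2 = (N - R) / (N + 2.4 R + 1)
    SAVI = (1 + L)(N - R) / (N + R + L)

with L the canopy background adjustment factor (default 0.5).
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .spectra import SpectraError, SpectralCurve

__all__ = [
    "VIConfig",
    "BandReflectance",
    "VIRecord",
    "band_average",
    "compute_indices",
    "indices_from_spectrum",
]


@dataclasses.dataclass(frozen=True)
class VIConfig:
    """Band windows (nm, closed intervals) and the SAVI L factor."""

    blue_band: tuple[float, float] = (459.0, 479.0)
    red_band: tuple[float, float] = (620.0, 670.0)
    nir_band: tuple[float, float] = (841.0, 876.0)
    savi_L: float = 0.5

    def __post_init__(self) -> None:
        bands = {"blue": self.blue_band, "red": self.red_band,
                 "nir": self.nir_band}
        for name, (lo, hi) in bands.items():
            if not lo < hi:
                raise SpectraError(f"{name} band must satisfy min < max")
        ordered = sorted(bands.values())
        for (lo1, hi1), (lo2, hi2) in zip(ordered[:-1], ordered[1:]):
            if lo2 <= hi1:
                raise SpectraError("band windows must be disjoint")


@dataclasses.dataclass(frozen=True)
class BandReflectance:
    """Blue/red/NIR band-mean reflectances."""

    r_blue: float
    r_red: float
    r_nir: float

    def __post_init__(self) -> None:
        for name in ("r_blue", "r_red", "r_nir"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpectraError(f"{name} outside [0, 1]: {v}")


@dataclasses.dataclass(frozen=True)
class VIRecord:
    """The four vegetation indices of one scenario."""

    ndvi: float
    evi: float
    evi2: float
    savi: float

    def __post_init__(self) -> None:
        vals = [self.ndvi, self.evi, self.evi2, self.savi]
        if not all(np.isfinite(vals)):
            raise SpectraError("non-finite vegetation index")
        if not -1.0 - 1e-9 <= self.ndvi <= 1.0 + 1e-9:
            raise SpectraError(f"NDVI outside [-1, 1]: {self.ndvi}")


def band_average(reflectance: SpectralCurve, band: tuple[float, float]) -> float:
    """Unweighted mean of samples with band_min <= lambda <= band_max."""
    lo, hi = band
    wl = reflectance.wavelengths_nm
    if lo < wl[0] - 1e-9 or hi > wl[-1] + 1e-9:
        raise SpectraError(
            f"band [{lo:.0f}, {hi:.0f}] nm outside curve range "
            f"[{wl[0]:.0f}, {wl[-1]:.0f}] nm"
        )
    mask = reflectance.band_mask(band)
    if not mask.any():
        raise SpectraError(f"no grid samples inside band [{lo:.0f}, {hi:.0f}] nm")
    return float(np.mean(reflectance.values[mask]))


def compute_indices(bands: BandReflectance, cfg: VIConfig | None = None) -> VIRecord:
    """NDVI, EVI, EVI2 and SAVI from band reflectances."""
    cfg = cfg or VIConfig()
    n, r, b = bands.r_nir, bands.r_red, bands.r_blue
    length = cfg.savi_L

    def _ratio(num: float, den: float, name: str) -> float:
        if abs(den) < 1e-12:
            raise SpectraError(f"zero denominator in {name}")
        return num / den

    return VIRecord(
        ndvi=_ratio(n - r, n + r, "NDVI"),
        evi=_ratio(2.5 * (n - r), n + 6.0 * r - 7.5 * b + 1.0, "EVI"),
        evi2=_ratio(n - r, n + 2.4 * r + 1.0, "EVI2"),
        savi=_ratio((1.0 + length) * (n - r), n + r + length, "SAVI"),
    )


def indices_from_spectrum(reflectance: SpectralCurve,
                          cfg: VIConfig | None = None
                          ) -> tuple[BandReflectance, VIRecord]:
    """Convolve a reflectance spectrum into bands and compute the indices."""
    cfg = cfg or VIConfig()
    bands = BandReflectance(
        r_blue=band_average(reflectance, cfg.blue_band),
        r_red=band_average(reflectance, cfg.red_band),
        r_nir=band_average(reflectance, cfg.nir_band),
    )
    return bands, compute_indices(bands, cfg)
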