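"""Per-layer absorbed fractions and green/non-green FPAR partitioning.

A layer's spectral absorbed fraction is the net-flux balance across its
two boundaries: what enters (direct beam plus downward diffuse minus
upward diffuse) at the top minus the same combination at the bottom,
normalised by the irradiance incident on the canopy.  Summing the
400-700 nm mean over leaf layers gives the green FPAR (the part of
absorbed PAR available for photosynthesis); branch layers give the
non-photosynthetic part.  Soil absorption is background, not canopy,
and is excluded from FPAR.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .sail import CanopyStack, FluxProfile, SailError
from .spectra import ComponentKind, PAR_BAND, SpectralCurve

__all__ = [
    "FparResult",
    "layer_absorbed_fraction",
    "fpar_from_absorption",
    "partition_canopy_fpar",
]


@dataclasses.dataclass(frozen=True)
class FparResult:
    """Total, green (PAV) and non-green (NPV) FPAR of one scenario."""

    fpar_total: float
    fpar_pav: float
    fpar_npv: float

    def __post_init__(self) -> None:
        for name in ("fpar_total", "fpar_pav", "fpar_npv"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1 + 1e-9:
                raise SailError(f"{name} outside [0, 1]: {v}")
        if abs(self.fpar_pav + self.fpar_npv - self.fpar_total) > 1e-10:
            raise SailError("fpar_pav + fpar_npv must equal fpar_total")


def layer_absorbed_fraction(profile: FluxProfile, layer_index: int) -> SpectralCurve:
    """Spectral fraction of incident irradiance absorbed by one layer.

    ``layer_index`` is 1-based from the top, matching the boundary
    numbering (boundary i is the top of layer i).
    """
    n = profile.n_layers
    if not 1 <= layer_index <= n:
        raise SailError(f"layer_index {layer_index} out of range 1..{n}")
    i = layer_index - 1
    net = profile.es + profile.e_down - profile.e_up   # (n_wl, N+1)
    absorbed = net[:, i] - net[:, i + 1]
    inc = profile.incident
    frac = np.where(inc > 0, absorbed / np.where(inc > 0, inc, 1.0), 0.0)
    return SpectralCurve(profile.wavelengths_nm, frac)


def fpar_from_absorption(absorption: SpectralCurve,
                         weighting: SpectralCurve | None = None) -> float:
    """Collapse a spectral absorbed fraction to a single FPAR value.

    Uniform mean over 400-700 nm by default; an incident-irradiance
    weighting may be supplied (interpolated and renormalised over PAR).
    """
    wl = absorption.wavelengths_nm
    if wl[0] > PAR_BAND[0] + 1e-9 or wl[-1] < PAR_BAND[1] - 1e-9:
        raise SailError(
            f"absorption grid [{wl[0]:.0f}, {wl[-1]:.0f}] nm does not cover PAR"
        )
    mask = absorption.band_mask(PAR_BAND)
    vals = absorption.values[mask]
    if weighting is None:
        return float(np.mean(vals))
    w = np.interp(wl[mask], weighting.wavelengths_nm, weighting.values)
    total = np.sum(w)
    if total <= 0:
        raise SailError("weighting integrates to zero over PAR")
    return float(np.sum(vals * w) / total)


def partition_canopy_fpar(profile: FluxProfile, stack: CanopyStack,
                          weighting: SpectralCurve | None = None) -> FparResult:
    """Split canopy FPAR into green (leaf-layer) and non-green parts."""
    if profile.n_layers != len(stack.layers):
        raise SailError(
            f"profile has {profile.n_layers} layers but stack has "
            f"{len(stack.layers)}"
        )
    if not np.array_equal(profile.wavelengths_nm, stack.wavelengths_nm):
        raise SailError("profile and stack wavelength grids differ")
    pav = 0.0
    npv = 0.0
    for idx, layer in enumerate(stack.layers, start=1):
        value = fpar_from_absorption(
            layer_absorbed_fraction(profile, idx), weighting
        )
        if layer.component.kind is ComponentKind.LEAF:
            pav += value
        else:
            npv += value
    # clip sub-1e-12 negatives from float cancellation in near-empty layers
    pav = max(pav, 0.0)
    npv = max(npv, 0.0)
    return FparResult(fpar_total=pav + npv, fpar_pav=pav, fpar_npv=npv)
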