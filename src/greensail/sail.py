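"""Four-stream SAIL radiative transfer for stacked single-component layers.

The canopy is a vertical stack of homogeneous turbid layers, each made of
one component (green leaf or woody element) with its own optical
properties and leaf inclination distribution, above a Lambertian soil.
Four fluxes are tracked per wavelength: the direct solar beam ``Es``,
downward diffuse ``E-``, upward diffuse ``E+`` and the flux toward the
viewer ``E0``.  With ``x`` the cumulative downward one-sided area index,
the transfer equations inside a layer are

    dEs/dx = -k Es
    dE-/dx =  s  Es - a E- + sigma E+
    dE+/dx = -s' Es - sigma E- + a E+     (E+ travels upward)
    dE0/dx = -w Es - v E- - u E+ + K E0   (E0 travels toward the viewer)

with extinction/scattering coefficients per unit area index derived from
the component reflectance/transmittance and the inclination distribution
following Verhoef's SAIL geometric factors.  Each layer admits an
analytic solution (diffuse eigenvalue m = sqrt(a^2 - sigma^2) plus a
direct-beam particular solution); integration constants are fixed by
flux continuity at the interior boundaries and the Lambertian soil
condition.  A finite-difference solver of the same boundary-value
problem is provided as an independent numerical oracle.
"""
from __future__ import annotations

import dataclasses
import functools
from typing import Sequence

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .spectra import ComponentKind, ComponentOptics

__all__ = [
    "Geometry",
    "CanopyLayer",
    "CanopyStack",
    "CoefficientSet",
    "FluxProfile",
    "SailError",
    "g_projection",
    "sail_coefficients",
    "solve_stack",
    "fd_oracle_solve",
]

#: Minimum allowed a - sigma; enforces a strictly positive diffuse
#: eigenvalue so the exponential layer basis stays non-degenerate even
#: for conservative scattering (rho + tau = 1).
_MIN_A_MINUS_SIGMA = 1e-9

#: Relative half-width of the resonance window |m - k| inside which the
#: direct-beam particular solution is evaluated by symmetric detuning.
_RESONANCE_TOL = 1e-4


class SailError(ValueError):
    """Invalid geometry/optics or a singular radiative-transfer system."""


# ---------------------------------------------------------------------------
# Geometry and canopy description
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Geometry:
    """Sun/view geometry and the direct fraction of incident irradiance."""

    solar_zenith_deg: float = 30.0
    view_zenith_deg: float = 0.0
    relative_azimuth_deg: float = 0.0
    direct_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.solar_zenith_deg < 90.0:
            raise SailError("solar zenith must be in [0, 90) degrees")
        if not 0.0 <= self.view_zenith_deg < 90.0:
            raise SailError("view zenith must be in [0, 90) degrees")
        if not 0.0 <= self.direct_fraction <= 1.0:
            raise SailError("direct_fraction must be in [0, 1]")


_DEFAULT_LIDF = {
    ComponentKind.LEAF: "spherical",
    ComponentKind.BRANCH: "planophile",
    ComponentKind.SOIL: "spherical",
}


@dataclasses.dataclass(frozen=True)
class CanopyLayer:
    """One homogeneous single-component layer.

    ``area_index`` is the one-sided component area per unit ground area.
    The inclination distribution defaults to spherical for leaves and
    planophile for woody elements.
    """

    component: ComponentOptics
    area_index: float
    lidf: str | None = None

    def __post_init__(self) -> None:
        if self.area_index < 0:
            raise SailError("area_index must be >= 0")
        if self.component.kind is ComponentKind.SOIL:
            raise SailError("soil cannot be a canopy layer")
        lidf = self.lidf or _DEFAULT_LIDF[self.component.kind]
        if lidf not in _LIDF_DENSITIES:
            raise SailError(f"unknown LIDF {lidf!r}; known: {sorted(_LIDF_DENSITIES)}")
        object.__setattr__(self, "lidf", lidf)


@dataclasses.dataclass(frozen=True)
class CanopyStack:
    """Ordered top-to-bottom layers over a Lambertian soil."""

    layers: tuple[CanopyLayer, ...]
    soil: ComponentOptics

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.soil.kind is not ComponentKind.SOIL:
            raise SailError("stack background must be a soil component")
        wl = self.soil.wavelengths_nm
        for i, layer in enumerate(self.layers):
            if not np.array_equal(layer.component.wavelengths_nm, wl):
                raise SailError(f"layer {i} grid differs from the soil grid")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.soil.wavelengths_nm

    @property
    def total_pai(self) -> float:
        return float(sum(l.area_index for l in self.layers))

    @property
    def green_proportion(self) -> float:
        total = self.total_pai
        if total == 0:
            return 0.0
        green = sum(
            l.area_index for l in self.layers
            if l.component.kind is ComponentKind.LEAF
        )
        return float(green / total)


# ---------------------------------------------------------------------------
# Leaf inclination distributions and geometric factors
# ---------------------------------------------------------------------------

#: Normalised inclination densities g(theta_l) on [0, pi/2].
_LIDF_DENSITIES = {
    "spherical": lambda t: np.sin(t),
    "planophile": lambda t: (2.0 / np.pi) * (1.0 + np.cos(2.0 * t)),
}


def _gauss_segments(breakpoints: Sequence[float], order: int = 64):
    """Gauss-Legendre nodes/weights over consecutive segments."""
    nodes, weights = np.polynomial.legendre.leggauss(order)
    xs, ws = [], []
    pts = sorted(set(float(b) for b in breakpoints))
    for lo, hi in zip(pts[:-1], pts[1:]):
        if hi - lo < 1e-12:
            continue
        half = 0.5 * (hi - lo)
        xs.append(half * nodes + 0.5 * (hi + lo))
        ws.append(half * weights)
    return np.concatenate(xs), np.concatenate(ws)


def _chi(theta_beam: float, theta_leaf: np.ndarray) -> np.ndarray:
    """Azimuthally averaged projection of unit leaf area onto a beam.

    For leaf/beam zenith combinations where the projection never changes
    sign over leaf azimuth this is cos(tl) cos(tb); otherwise the
    standard SAIL crossing correction applies.
    """
    cs = np.cos(theta_leaf) * np.cos(theta_beam)
    ss = np.sin(theta_leaf) * np.sin(theta_beam)
    with np.errstate(divide="ignore", invalid="ignore"):
        cosb = np.where(np.abs(ss) > 1e-12, -cs / ss, 5.0)
    crossing = np.abs(cosb) < 1.0
    b = np.where(crossing, np.arccos(np.clip(cosb, -1.0, 1.0)), np.pi)
    return (2.0 / np.pi) * ((b - 0.5 * np.pi) * cs + np.sin(b) * ss)


def g_projection(lidf: str, zenith_deg: float) -> float:
    """G-function: mean projected component area for a beam at ``zenith_deg``.

    Satisfies the hemispheric identity (1/2) int G(theta) sin(theta)
    dtheta = 1/2; for the spherical distribution G = 1/2 exactly at all
    angles.
    """
    if lidf not in _LIDF_DENSITIES:
        raise SailError(f"unknown LIDF {lidf!r}; known: {sorted(_LIDF_DENSITIES)}")
    if not 0.0 <= zenith_deg < 90.0:
        raise SailError("zenith must be in [0, 90) degrees")
    tb = np.deg2rad(zenith_deg)
    breaks = [0.0, np.pi / 2]
    kink = np.pi / 2 - tb
    if 0.0 < kink < np.pi / 2:
        breaks.append(kink)
    tl, w = _gauss_segments(breaks)
    g = _LIDF_DENSITIES[lidf](tl)
    return float(np.sum(w * g * _chi(tb, tl)))


def _volscatt(tts: float, tto: float, psi: float, ttl: np.ndarray):
    """Verhoef's volume-scattering geometry kernel.

    Returns (frho, ftau): the bidirectional scattering weights that,
    combined with component rho/tau, give the contribution of the solar
    beam to the viewer-direction flux.
    """
    costs, costo = np.cos(tts), np.cos(tto)
    sints, sinto = np.sin(tts), np.sin(tto)
    cospsi = np.cos(psi)
    costl, sintl = np.cos(ttl), np.sin(ttl)
    cs, co = costl * costs, costl * costo
    ss, so = sintl * sints, sintl * sinto

    with np.errstate(divide="ignore", invalid="ignore"):
        cosbts = np.where(np.abs(ss) > 1e-6, -cs / ss, 5.0)
        cosbto = np.where(np.abs(so) > 1e-6, -co / so, 5.0)

    bts = np.where(np.abs(cosbts) < 1.0,
                   np.arccos(np.clip(cosbts, -1, 1)), np.pi)
    ds = np.where(np.abs(cosbts) < 1.0, ss, cs)
    bto = np.where(np.abs(cosbto) < 1.0,
                   np.arccos(np.clip(cosbto, -1, 1)),
                   np.pi if tto < np.pi / 2 else 0.0)
    do_ = np.where(np.abs(cosbto) < 1.0, so,
                   co if tto < np.pi / 2 else -co)

    btran1 = np.abs(bts - bto)
    btran2 = np.pi - np.abs(bts + bto - np.pi)
    use1 = psi <= btran1
    use2 = psi <= btran2
    bt1 = np.where(use1, psi, btran1)
    bt2 = np.where(use1, btran1, np.where(use2, psi, btran2))
    bt3 = np.where(use1, btran2, np.where(use2, btran2, psi))

    t1 = 2.0 * cs * co + ss * so * cospsi
    t2 = np.where(
        bt2 > 0.0,
        np.sin(bt2) * (2.0 * ds * do_ + ss * so * np.cos(bt1) * np.cos(bt3)),
        0.0,
    )
    denom = 2.0 * np.pi ** 2
    frho = np.maximum(((np.pi - bt2) * t1 + t2) / denom, 0.0)
    ftau = np.maximum((-bt2 * t1 + t2) / denom, 0.0)
    return frho, ftau


@functools.lru_cache(maxsize=256)
def _geometry_factors(lidf: str, tts_deg: float, tto_deg: float, psi_deg: float):
    """LIDF-integrated geometric factors (k, K, bf, sob, sof)."""
    tts, tto, psi = np.deg2rad([tts_deg, tto_deg, abs(psi_deg) % 360.0])
    if psi > np.pi:
        psi = 2.0 * np.pi - psi
    breaks = [0.0, np.pi / 2]
    for kink in (np.pi / 2 - tts, np.pi / 2 - tto):
        if 0.0 < kink < np.pi / 2:
            breaks.append(kink)
    tl, w = _gauss_segments(breaks)
    g = _LIDF_DENSITIES[lidf](tl)
    k = float(np.sum(w * g * _chi(tts, tl)) / np.cos(tts))
    kk = float(np.sum(w * g * _chi(tto, tl)) / np.cos(tto))
    bf = float(np.sum(w * g * np.cos(tl) ** 2))
    frho, ftau = _volscatt(tts, tto, psi, tl)
    scale = np.pi / (np.cos(tts) * np.cos(tto))
    sob = float(np.sum(w * g * frho) * scale)
    sof = float(np.sum(w * g * ftau) * scale)
    return k, kk, bf, sob, sof


# ---------------------------------------------------------------------------
# Per-wavelength SAIL coefficients
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CoefficientSet:
    """SAIL coefficients per unit area index.

    ``k``/``K`` (direct-beam and viewer-path extinction) depend only on
    geometry and the LIDF; the scattering coefficients are linear in the
    component reflectance/transmittance and are arrays over wavelength.
    """

    k: float
    K: float
    a: np.ndarray
    sigma: np.ndarray
    s: np.ndarray          # direct -> downward diffuse
    s_prime: np.ndarray    # direct -> upward diffuse
    u: np.ndarray          # upward diffuse -> viewer
    v: np.ndarray          # downward diffuse -> viewer
    w: np.ndarray          # direct -> viewer (bidirectional)


def sail_coefficients(optics: ComponentOptics, lidf: str,
                      geom: Geometry) -> CoefficientSet:
    """Compute SAIL coefficients for one component under one geometry."""
    if lidf not in _LIDF_DENSITIES:
        raise SailError(f"unknown LIDF {lidf!r}; known: {sorted(_LIDF_DENSITIES)}")
    ks, ko, bf, sob, sof = _geometry_factors(
        lidf, float(geom.solar_zenith_deg), float(geom.view_zenith_deg),
        float(geom.relative_azimuth_deg),
    )
    rho = optics.reflectance.values
    tau = optics.transmittance.values
    sdb, sdf = 0.5 * (ks + bf), 0.5 * (ks - bf)
    ddb, ddf = 0.5 * (1.0 + bf), 0.5 * (1.0 - bf)
    dob, dof = 0.5 * (ko + bf), 0.5 * (ko - bf)

    sigb = ddb * rho + ddf * tau
    sigf = ddf * rho + ddb * tau
    a = 1.0 - sigf
    # keep the diffuse eigenvalue strictly positive at conservative
    # scattering (rho + tau = 1 gives a = sigma exactly)
    sigma = np.minimum(sigb, a - _MIN_A_MINUS_SIGMA)
    if np.any(a * a < sigma * sigma):
        bad = int(np.argmax(a * a < sigma * sigma))
        raise SailError(
            f"non-physical optics (a^2 < sigma^2) at "
            f"{optics.wavelengths_nm[bad]:.1f} nm"
        )
    return CoefficientSet(
        k=ks,
        K=ko,
        a=a,
        sigma=sigma,
        s=sdf * rho + sdb * tau,
        s_prime=sdb * rho + sdf * tau,
        u=dof * rho + dob * tau,
        v=dob * rho + dof * tau,
        w=sob * rho + sof * tau,
    )


# ---------------------------------------------------------------------------
# Flux profile container
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FluxProfile:
    """Boundary fluxes of a solved stack.

    Boundary 0 is the canopy top; boundary N the soil surface.  Flux
    arrays have shape (n_wavelengths, N+1).  ``reflectance_factor`` is
    the viewer-direction directional reflectance at the top.
    """

    wavelengths_nm: np.ndarray
    boundary_depths: np.ndarray      # cumulative downward area index, length N+1
    es: np.ndarray                   # direct (specular) downward flux
    e_down: np.ndarray               # diffuse downward flux
    e_up: np.ndarray                 # diffuse upward flux
    incident: np.ndarray             # total incident irradiance per wavelength
    reflectance_factor: np.ndarray

    @property
    def n_layers(self) -> int:
        return int(self.boundary_depths.size - 1)


def _as_incident(incident, n_wl: int) -> np.ndarray:
    arr = np.asarray(incident, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_wl, float(arr))
    if arr.shape != (n_wl,):
        raise SailError(f"incident must be scalar or length {n_wl}")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise SailError("incident irradiance must be finite and >= 0")
    return arr


# ---------------------------------------------------------------------------
# Analytic multi-layer solution
# ---------------------------------------------------------------------------

def _layer_fields(coeffs, n_wl):
    """Per-layer arrays (N, n_wl) of a, sigma, s, s', k, m."""
    a = np.stack([c.a for c in coeffs])
    sigma = np.stack([c.sigma for c in coeffs])
    s = np.stack([c.s for c in coeffs])
    sp = np.stack([c.s_prime for c in coeffs])
    k = np.stack([np.full(n_wl, c.k) for c in coeffs])
    m = np.sqrt(np.maximum(a * a - sigma * sigma, 0.0))
    return a, sigma, s, sp, k, m


def _particular(a, sigma, s, sp, k, m):
    """Direct-beam particular solution (P, Q) with Es(t) = Es_top e^{-kt}."""
    det = m * m - k * k
    p = (s * (a + k) + sp * sigma) / det
    q = (sp * (a - k) + s * sigma) / det
    return p, q


def _solve_pass(a, sigma, s, sp, k, m, lengths, rs, es_top, ed_top):
    """One analytic solve for given (possibly detuned) k.

    Returns per-layer mode amplitudes (A, B), particular (P, Q) and the
    direct flux at each boundary; shapes (N, n_wl).
    """
    n_layers, n_wl = a.shape
    gamma = sigma / (a + m)
    p, q = _particular(a, sigma, s, sp, k, m)

    # direct beam at each boundary, exact per layer
    kl = k * lengths[:, None]
    es_b = np.empty((n_layers + 1, n_wl))
    es_b[0] = es_top
    np.cumsum(kl, axis=0, out=kl)
    es_b[1:] = es_top[None, :] * np.exp(-kl)

    em = np.exp(-m * lengths[:, None])
    ep = np.exp(m * lengths[:, None])

    mat = np.zeros((n_wl, 2 * n_layers, 2 * n_layers))
    rhs = np.zeros((n_wl, 2 * n_layers))

    # top boundary: downward diffuse prescribed
    mat[:, 0, 0] = 1.0
    mat[:, 0, 1] = gamma[0]
    rhs[:, 0] = ed_top - p[0] * es_b[0]

    for i in range(n_layers - 1):
        r1, r2 = 2 * i + 1, 2 * i + 2
        ca, cb = 2 * i, 2 * i + 1
        na, nb = 2 * i + 2, 2 * i + 3
        # E- continuity at boundary i+1
        mat[:, r1, ca] = em[i]
        mat[:, r1, cb] = gamma[i] * ep[i]
        mat[:, r1, na] = -1.0
        mat[:, r1, nb] = -gamma[i + 1]
        rhs[:, r1] = (p[i + 1] - p[i]) * es_b[i + 1]
        # E+ continuity at boundary i+1
        mat[:, r2, ca] = gamma[i] * em[i]
        mat[:, r2, cb] = ep[i]
        mat[:, r2, na] = -gamma[i + 1]
        mat[:, r2, nb] = -1.0
        rhs[:, r2] = (q[i + 1] - q[i]) * es_b[i + 1]

    # soil: E+ = rs (Es + E-) at the bottom
    i = n_layers - 1
    mat[:, -1, 2 * i] = (gamma[i] - rs) * em[i]
    mat[:, -1, 2 * i + 1] = (1.0 - rs * gamma[i]) * ep[i]
    rhs[:, -1] = es_b[-1] * (rs * (1.0 + p[i]) - q[i])

    try:
        sol = np.linalg.solve(mat, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        resid = [np.linalg.cond(mat[j]) for j in range(n_wl)]
        bad = int(np.argmax(resid))
        raise SailError(f"singular interface system at wavelength index {bad}") from exc
    amp_a = sol[:, 0::2].T  # (N, n_wl)
    amp_b = sol[:, 1::2].T
    return amp_a, amp_b, p, q, gamma, es_b, em, ep


def _boundary_fluxes(amp_a, amp_b, p, q, gamma, es_b, em, ep):
    n_layers, n_wl = amp_a.shape
    e_down = np.empty((n_layers + 1, n_wl))
    e_up = np.empty((n_layers + 1, n_wl))
    # tops of each layer
    e_down[:-1] = amp_a + gamma * amp_b + p * es_b[:-1]
    e_up[:-1] = gamma * amp_a + amp_b + q * es_b[:-1]
    # bottom of the last layer
    i = n_layers - 1
    e_down[-1] = amp_a[i] * em[i] + gamma[i] * amp_b[i] * ep[i] + p[i] * es_b[-1]
    e_up[-1] = gamma[i] * amp_a[i] * em[i] + amp_b[i] * ep[i] + q[i] * es_b[-1]
    return e_down, e_up


_E0_GAUSS = np.polynomial.legendre.leggauss(48)


def _viewer_flux(amp_a, amp_b, p, q, gamma, es_b, k_arr, m, lengths, coeffs,
                 rs, e_down_bottom):
    """Top-of-canopy viewer-direction flux by per-layer quadrature.

    Integrates the source w Es + v E- + u E+ against the viewer-path
    transmittance, starting from the Lambertian soil radiance.  All
    layer fields (amplitudes, particular solution, detuned k) come from
    the analytic pass they belong to.
    """
    n_layers, n_wl = amp_a.shape
    e0 = rs * (es_b[-1] + e_down_bottom)  # flux-equivalent soil radiance
    nodes, weights = _E0_GAUSS
    for i in range(n_layers - 1, -1, -1):
        c = coeffs[i]
        length = lengths[i]
        if length == 0.0:
            continue
        t = 0.5 * length * (nodes + 1.0)          # (nq,)
        wq = 0.5 * length * weights
        es_t = es_b[i][None, :] * np.exp(-t[:, None] * k_arr[i][None, :])
        emt = np.exp(-t[:, None] * m[i][None, :])
        ept = np.exp(t[:, None] * m[i][None, :])
        e_minus = (amp_a[i][None, :] * emt
                   + gamma[i][None, :] * amp_b[i][None, :] * ept
                   + p[i][None, :] * es_t)
        e_plus = (gamma[i][None, :] * amp_a[i][None, :] * emt
                  + amp_b[i][None, :] * ept
                  + q[i][None, :] * es_t)
        source = c.w[None, :] * es_t + c.v[None, :] * e_minus + c.u[None, :] * e_plus
        integral = np.sum(wq[:, None] * source * np.exp(-c.K * t)[:, None], axis=0)
        e0 = e0 * np.exp(-c.K * length) + integral
    return e0


def solve_stack(stack: CanopyStack, geom: Geometry,
                incident: float | np.ndarray = 1.0) -> FluxProfile:
    """Solve the four-stream boundary-value problem for a layered canopy.

    Returns all boundary fluxes plus the viewer-direction directional
    reflectance factor.  Wavelengths where the direct-beam extinction
    resonates with the diffuse eigenvalue (k ~ m) are handled by
    averaging two slightly detuned solves, a second-order-accurate
    evaluation of the removable singularity.
    """
    wl = stack.wavelengths_nm
    n_wl = wl.size
    inc = _as_incident(incident, n_wl)
    es_top = geom.direct_fraction * inc
    ed_top = (1.0 - geom.direct_fraction) * inc
    rs = stack.soil.reflectance.values
    layers = stack.layers
    depths = np.concatenate([[0.0], np.cumsum([l.area_index for l in layers])])

    if len(layers) == 0 or stack.total_pai == 0.0:
        n_b = len(layers) + 1
        es = np.tile(es_top, (n_b, 1))
        e_down = np.tile(ed_top, (n_b, 1))
        e_up = np.tile(rs * (es_top + ed_top), (n_b, 1))
        refl = np.where(inc > 0, rs, 0.0)
        return FluxProfile(wl, depths, es.T, e_down.T, e_up.T, inc, refl)

    coeffs = [sail_coefficients(l.component, l.lidf, geom) for l in layers]
    lengths = np.array([l.area_index for l in layers], dtype=float)
    a, sigma, s, sp, k, m = _layer_fields(coeffs, n_wl)

    resonant = np.abs(m - k) < _RESONANCE_TOL * np.maximum(k, 1.0)
    if resonant.any():
        wl_mask = resonant.any(axis=0)
        halves = []
        for sign in (+1.0, -1.0):
            k_d = k.copy()
            k_d[:, wl_mask] = k[:, wl_mask] * (1.0 + sign * _RESONANCE_TOL)
            aa, bb, p_, q_, g_, esb, em, ep = _solve_pass(
                a, sigma, s, sp, k_d, m, lengths, rs, es_top, ed_top
            )
            ed, eu = _boundary_fluxes(aa, bb, p_, q_, g_, esb, em, ep)
            e0_half = _viewer_flux(aa, bb, p_, q_, g_, esb, k_d, m, lengths,
                                   coeffs, rs, ed[-1])
            halves.append((ed, eu, esb, e0_half))
        e_down = 0.5 * (halves[0][0] + halves[1][0])
        e_up = 0.5 * (halves[0][1] + halves[1][1])
        es_b = 0.5 * (halves[0][2] + halves[1][2])
        e0 = 0.5 * (halves[0][3] + halves[1][3])
    else:
        amp_a, amp_b, p, q, gamma, es_b, em, ep = _solve_pass(
            a, sigma, s, sp, k, m, lengths, rs, es_top, ed_top
        )
        e_down, e_up = _boundary_fluxes(amp_a, amp_b, p, q, gamma, es_b, em, ep)
        e0 = _viewer_flux(amp_a, amp_b, p, q, gamma, es_b, k, m, lengths,
                          coeffs, rs, e_down[-1])

    with np.errstate(divide="ignore", invalid="ignore"):
        refl = np.where(inc > 0, e0 / np.where(inc > 0, inc, 1.0), 0.0)
    return FluxProfile(
        wavelengths_nm=wl,
        boundary_depths=depths,
        es=es_b.T,
        e_down=e_down.T,
        e_up=e_up.T,
        incident=inc,
        reflectance_factor=refl,
    )


# ---------------------------------------------------------------------------
# Finite-difference oracle
# ---------------------------------------------------------------------------

def fd_oracle_solve(stack: CanopyStack, geom: Geometry,
                    incident: float | np.ndarray = 1.0,
                    n_steps: int = 10_000) -> FluxProfile:
    """Independent finite-difference solution of the same boundary-value
    problem.

    Discretises the diffuse two-stream system on a fine depth grid with
    the trapezoidal (second-order) scheme and solves the resulting
    sparse linear system per wavelength; the direct beam is evaluated
    analytically.  Intended as a verification oracle; much slower than
    :func:`solve_stack`.
    """
    if n_steps < 1000:
        raise SailError("fd oracle requires n_steps >= 1000")
    wl = stack.wavelengths_nm
    n_wl = wl.size
    inc = _as_incident(incident, n_wl)
    es_top = geom.direct_fraction * inc
    ed_top = (1.0 - geom.direct_fraction) * inc
    rs = stack.soil.reflectance.values
    layers = stack.layers
    depths = np.concatenate([[0.0], np.cumsum([l.area_index for l in layers])])
    total = depths[-1]

    if len(layers) == 0 or total == 0.0:
        return solve_stack(stack, geom, incident)

    coeffs = [sail_coefficients(l.component, l.lidf, geom) for l in layers]
    lengths = np.array([l.area_index for l in layers], dtype=float)

    # node grid: layer boundaries are nodes; steps proportional to thickness
    steps = np.maximum((n_steps * lengths / total).astype(int), 1)
    nodes = [np.array([0.0])]
    layer_of_interval = []
    for i, (length, ns) in enumerate(zip(lengths, steps)):
        local = depths[i] + (length / ns) * np.arange(1, ns + 1)
        nodes.append(local)
        layer_of_interval.extend([i] * ns)
    x = np.concatenate(nodes)
    layer_of_interval = np.asarray(layer_of_interval)
    n_nodes = x.size
    boundary_idx = np.concatenate([[0], np.cumsum(steps)])

    # direct beam, exact
    k_per_layer = np.array([c.k for c in coeffs])
    tau_direct = np.concatenate([[0.0], np.cumsum(k_per_layer * lengths)])
    es_x = np.empty((n_nodes, n_wl))
    for i in range(len(layers)):
        sel = slice(boundary_idx[i], boundary_idx[i + 1] + 1)
        es_x[sel] = es_top[None, :] * np.exp(
            -(tau_direct[i] + k_per_layer[i] * (x[sel] - depths[i]))[:, None]
        )

    h = np.diff(x)
    li = layer_of_interval
    a_l = np.stack([c.a for c in coeffs])[li]        # (n_int, n_wl)
    sg_l = np.stack([c.sigma for c in coeffs])[li]
    s_l = np.stack([c.s for c in coeffs])[li]
    sp_l = np.stack([c.s_prime for c in coeffs])[li]

    e_down = np.empty((n_nodes, n_wl))
    e_up = np.empty((n_nodes, n_wl))
    n_unknown = 2 * n_nodes
    idx_dn = np.arange(n_nodes) * 2
    idx_up = idx_dn + 1

    for j in range(n_wl):
        rows, cols, vals = [], [], []
        rhs = np.zeros(n_unknown)

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        # top: E-(0) prescribed
        add(0, idx_dn[0], 1.0)
        rhs[0] = ed_top[j]
        # bottom: E+(L) - rs E-(L) = rs Es(L)
        add(1, idx_up[-1], 1.0)
        add(1, idx_dn[-1], -rs[j])
        rhs[1] = rs[j] * es_x[-1, j]

        r = 2
        for i in range(n_nodes - 1):
            hh = 0.5 * h[i]
            a_, sg_, s_, sp_ = a_l[i, j], sg_l[i, j], s_l[i, j], sp_l[i, j]
            src = s_ * (es_x[i, j] + es_x[i + 1, j])
            # trapezoid for dE-/dx = -a E- + sigma E+ + s Es
            add(r, idx_dn[i + 1], 1.0 + hh * a_)
            add(r, idx_dn[i], -1.0 + hh * a_)
            add(r, idx_up[i + 1], -hh * sg_)
            add(r, idx_up[i], -hh * sg_)
            rhs[r] = hh * src
            r += 1
            # trapezoid for dE+/dx = a E+ - sigma E- - s' Es
            add(r, idx_up[i + 1], 1.0 - hh * a_)
            add(r, idx_up[i], -1.0 - hh * a_)
            add(r, idx_dn[i + 1], hh * sg_)
            add(r, idx_dn[i], hh * sg_)
            rhs[r] = -hh * sp_ * (es_x[i, j] + es_x[i + 1, j])
            r += 1

        mat = scipy.sparse.csr_matrix(
            (vals, (rows, cols)), shape=(n_unknown, n_unknown)
        )
        try:
            sol = scipy.sparse.linalg.spsolve(mat, rhs)
        except RuntimeError as exc:  # pragma: no cover - singular system
            raise SailError(
                f"fd oracle failed at wavelength {wl[j]:.1f} nm"
            ) from exc
        if not np.all(np.isfinite(sol)):
            raise SailError(f"fd oracle diverged at wavelength {wl[j]:.1f} nm")
        e_down[:, j] = sol[idx_dn]
        e_up[:, j] = sol[idx_up]

    # viewer flux by trapezoid along the same grid
    k_view = np.array([c.K for c in coeffs])[li]
    w_l = np.stack([c.w for c in coeffs])[li]
    v_l = np.stack([c.v for c in coeffs])[li]
    u_l = np.stack([c.u for c in coeffs])[li]
    e0 = rs * (es_x[-1] + e_down[-1])
    for i in range(n_nodes - 2, -1, -1):
        src_lo = (w_l[i] * es_x[i] + v_l[i] * e_down[i] + u_l[i] * e_up[i])
        src_hi = (w_l[i] * es_x[i + 1] + v_l[i] * e_down[i + 1]
                  + u_l[i] * e_up[i + 1])
        att = np.exp(-k_view[i] * h[i])
        e0 = e0 * att + 0.5 * h[i] * (src_lo * att + src_hi)

    with np.errstate(divide="ignore", invalid="ignore"):
        refl = np.where(inc > 0, e0 / np.where(inc > 0, inc, 1.0), 0.0)
    return FluxProfile(
        wavelengths_nm=wl,
        boundary_depths=depths,
        es=es_x[boundary_idx].T,
        e_down=e_down[boundary_idx].T,
        e_up=e_up[boundary_idx].T,
        incident=inc,
        reflectance_factor=refl,
    )
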