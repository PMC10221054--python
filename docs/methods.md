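# Methods

## The problem

Forest canopies mix photosynthetically active vegetation (PAV — green
leaves) with non-photosynthetic vegetation (NPV — branches and stems).
Both absorb photosynthetically active radiation (PAR, 400–700 nm), but
only the PAR absorbed by leaves drives photosynthesis, so satellite
products that estimate the *total* fraction of absorbed PAR (FPAR)
overstate the photosynthetically useful flux, especially in open
canopies.  `greensail` implements a layered variant of the SAIL
turbid-medium radiative-transfer model in which every layer contains a
single component, so the absorbed flux — and hence FPAR — can be
attributed to leaves and woody elements separately, and relates the
resulting *green* FPAR to the spectral vegetation indices (NDVI, EVI,
EVI2, SAVI) that would be used to invert it from satellite reflectance.

## Radiative transfer model

The canopy is a stack of homogeneous layers over a Lambertian soil.
With `x` the cumulative downward one-sided area index, four fluxes are
tracked per wavelength — direct solar `Es`, downward diffuse `E-`,
upward diffuse `E+` and the viewer-direction flux `E0`:

    dEs/dx = -k Es
    dE-/dx =  s  Es - a E- + sigma E+
    dE+/dx = -s' Es - sigma E- + a E+
    dE0/dx = -w Es - v E- - u E+ + K E0

The coefficients per unit area index follow Verhoef's SAIL geometric
factors: `k = G(theta_s)/cos(theta_s)` and `K = G(theta_o)/cos(theta_o)`
from the leaf-inclination G-function, and the scattering coefficients
are linear combinations of the component reflectance and transmittance
weighted by LIDF moments (the `sdb/sdf`, `ddb/ddf`, `dob/dof` pairs and
the bidirectional `volscatt` kernel).  Two inclination distributions are
built in, the trigonometric densities `g = sin(theta_l)` (spherical,
used for leaves) and `g = (2/pi)(1 + cos 2 theta_l)` (planophile, used
for branches).  LIDF integrals are evaluated by Gauss–Legendre
quadrature split at the projection-sign kink angles, which makes the
spherical G-function exact to ~1e-10 and preserves the hemispheric
identity `(1/2)∫G sinθ dθ = 1/2` to the same accuracy.

Within a layer the diffuse system has the analytic solution
`A e^{-mt}(1, γ) + B e^{mt}(γ, 1)` with eigenvalue
`m = sqrt(a² - σ²)` and mode ratio `γ = σ/(a+m)`, plus a direct-beam
particular solution `∝ e^{-kt}`.  The mode amplitudes of all layers are
fixed simultaneously by a banded linear system: prescribed downward
diffuse flux at the top, continuity of `E-` and `E+` at every interior
boundary, and `E+ = r_s (Es + E-)` at the soil.  The system is solved
per wavelength as one batched `numpy` call.  The viewer-direction flux
is then obtained by integrating the source `w Es + v E- + u E+` against
the view-path transmittance `e^{-K x}` with 48-point Gauss–Legendre
quadrature per layer, starting from the Lambertian soil radiance; the
nadir directional reflectance factor is `E0(top)/incident`.

### Numerical choices

- **Conservative scattering.**  At `rho + tau = 1` the eigenvalue `m`
  vanishes and the two modes degenerate.  We clamp `a - sigma` to a
  floor of 1e-9, which keeps the basis non-degenerate at the cost of an
  absorption error below 1e-8 — the tolerance used by the
  energy-conservation tests.
- **Beam/diffuse resonance.**  When `k ≈ m` the particular solution has
  a removable singularity (`∝ 1/(m²-k²)`).  Wavelengths inside the
  window `|m-k| < 1e-4 max(k,1)` are solved twice with the beam
  extinction detuned by ±1e-4 and averaged; the averaging cancels the
  first-order detuning error, leaving an O(1e-8) bias.  Each detuned
  solve is internally flux-consistent, so energy conservation is exact.
- **Singular systems** (non-physical optics, `a² < σ²`) raise with the
  offending wavelength identified.
- **Verification oracle.**  `fd_oracle_solve` re-solves the same
  boundary-value problem with a second-order trapezoidal finite
  difference scheme on a fine depth grid (default 10,000 steps,
  layer boundaries aligned with grid nodes) and a sparse direct solve
  per wavelength.  On 50 random multi-layer stacks the worst boundary
  flux discrepancy against the analytic solver is below 1e-8.

## FPAR partitioning

A layer's spectral absorbed fraction is the net flux balance
`(Es + E- - E+)` at its top minus the same combination at its bottom,
divided by the incident top irradiance.  FPAR collapses this to a
scalar as the uniform mean over 400–700 nm (a user-supplied irradiance
weighting is accepted; none of the headline results use one, as a flat
weighting is the conventional default when no solar spectrum is
specified).  Green FPAR sums leaf layers, NPV FPAR sums branch layers;
soil absorption is background and excluded.  The split is exactly
additive by construction.

## Layer arrangement

The model needs an assumption about where leaves sit relative to
branches.  Two arrangements are provided:

- **blocks** (default): one leaf layer above one branch layer.  This
  mirrors real crowns, where foliage overtops and shades the woody
  skeleton, and it is the arrangement that reproduces the observed
  behaviour of woody-element FPAR: it rises with PAI while the thin
  leaf layer transmits most of the beam, peaks near PAI ≈ 2 at half
  greenness, and decays as the deepening leaf layer intercepts nearly
  everything.
- **interleaved**: `n_pairs` alternating thin leaf/branch sublayers
  (default 10), approximating a well-mixed canopy.  Here each
  component's absorption share stays roughly proportional to its area
  at every PAI, so NPV FPAR saturates instead of peaking.  This mode is
  kept for sensitivity analysis and for the identical-optics sanity
  check (with equal optics the green share of FPAR equals the green
  area fraction to < 0.01 at 40 pairs).

## Synthetic component spectra

Measured component spectra can be supplied as CSV
(`wavelength_nm, reflectance[, transmittance]`); when none are
available the generator builds them on the canonical 400–1000 nm / 5 nm
grid (121 samples, covering PAR and all index bands):

- **Leaves** are modelled through the single-scattering albedo.  The
  absorptance is `1 - (1-α_NIR) exp(-S · shape(λ))` where `shape` is a
  flat visible baseline plus Gaussian pigment wells at ~450 and ~670 nm,
  multiplied by a logistic red-edge switch (centre ≈ 715 nm, width
  ≈ 10 nm); `S` is root-solved so the mean 400–700 nm absorptance
  matches the profile target exactly (hence monotone in the target).
  Reflectance takes slightly more than half of the albedo in the
  visible.  Six species profiles are built in with PAR absorptance
  targets 0.900 (oak) > 0.885 (alder) > 0.876/0.875/0.874
  (spruce/aspen/hemlock) > 0.855 (juniper) — realistic laboratory leaf
  values whose ordering drives the species ranking of green FPAR —
  and NIR albedo 0.93–0.94 for broadleaves, 0.88–0.90 for conifers.
- **Bark and soil** are non-transmitting ramps (transmittance ≡ 0,
  consistent with woody elements absorbing whatever they do not
  reflect), levelled so the mean PAR absorptance hits the target:
  bark 0.72 (broadleaf) / 0.75 (conifer), soil a bright-ish dry ramp
  from 0.05 at 400 nm to 0.25 at 1000 nm.
- A seeded perturbation (three smooth sinusoids, ±0.4% amplitude)
  individualises curves without moving the calibrated PAR absorptance.

What the generator does *not* emulate: biochemical structure
(no PROSPECT-style plate model), water absorption features beyond
1000 nm, specular/structural effects, and the true covariance between
visible and NIR properties of real foliage.  Passing tests therefore
demonstrate the *model machinery* and the qualitative structure of the
FPAR–VI relations, not radiometric fidelity to any particular forest.

## Simulation study

Reference conditions: solar zenith 30°, nadir view, fully direct
irradiance.  The standard grid crosses plant area index
{0.1, 0.5, 1, 2, 3, 4, 5, 6, 7} with green proportions
{0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.98} (63 scenarios per forest class;
deciduous broadleaf uses the broadleaf mean leaf/bark spectra, evergreen
coniferous the needleleaf mean).  Vegetation indices use MODIS-like
bands (blue 459–479, red 620–670, NIR 841–876 nm), flat band response,
SAVI `L = 0.5`.

The inversion scenarios encode seasonal-structure priors: deciduous
forests keep a constant woody area index of 0.5 (the winter PAI of bare
deciduous stands) while PAI runs over the integers 1–7; coniferous
forests keep a constant green proportion of 90%.  Green FPAR is then
regressed on EVI by ordinary least squares; the reported error metrics
are the mean absolute residual and its ratio to the mean simulated green
FPAR (in percent).

Correlation tables pool all grid rows per forest class, with optional
per-proportion stratification.

## Known limitations

- Classical SAIL: no hotspot correction, no clumping, 1-D homogeneous
  layers only; thermal domain and polarization out of scope.
- The soil is Lambertian and spectrally fixed per run.
- Under the synthetic spectra, SAVI's correlation with green FPAR on the
  inversion scenarios is marginally (2e-4–2e-3) higher than EVI's;
  which index ranks first at that margin depends on the exact component
  spectra and background, so index *rankings* from synthetic runs
  should not be over-interpreted.
- Diffuse incident radiation is supported (`direct_fraction < 1`) with
  an isotropic two-stream treatment, but the reference scenarios are
  fully direct.
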