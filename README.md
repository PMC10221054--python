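# greensail

Layered SAIL canopy radiative transfer for partitioning the fraction of
absorbed photosynthetically active radiation (FPAR) between green leaves
and woody elements, and for relating the resulting *green FPAR* to
spectral vegetation indices.

## Why

Forest canopies absorb PAR (400–700 nm) with both photosynthetically
active vegetation (PAV: green leaves) and non-photosynthetic vegetation
(NPV: branches, stems).  Only the leaf-absorbed part fuels
photosynthesis, so gross-primary-production models driven by *total*
FPAR overestimate the useful flux — most severely in open, sparse
canopies.  `greensail` is aimed at vegetation remote-sensing researchers
who need a forward model of this partition: it solves the four-stream
SAIL transfer equations for a stack of single-component layers over a
Lambertian soil,

    dEs/dx = -k Es
    dE-/dx =  s  Es - a E- + sigma E+
    dE+/dx = -s' Es - sigma E- + a E+
    dE0/dx = -w Es - v E- - u E+ + K E0

(`Es` direct beam, `E∓` downward/upward diffuse flux, `E0` flux toward
the viewer, `x` cumulative downward area index), attributes the absorbed
PAR to each layer by flux balance, and computes NDVI, EVI, EVI2 and
SAVI from the simulated nadir reflectance:

    NDVI = (N-R)/(N+R)            EVI  = 2.5 (N-R)/(N + 6R - 7.5B + 1)
    EVI2 = (N-R)/(N + 2.4R + 1)   SAVI = (1+L)(N-R)/(N+R+L),  L = 0.5

A linear inversion `FPAR_PAV = slope × EVI + intercept` is fitted per
forest class (deciduous broadleaf DBF / evergreen coniferous ENF) on
scenarios that hold the seasonal canopy-structure priors fixed.
Component spectra can be read from CSV; a calibrated synthetic generator
(six species profiles, bark, soil) stands in when measurements are not
available.  See `docs/methods.md` for the model details.

## Worked example

```python
import greensail as gs
from greensail.experiments import (
    default_scenario_config, run_scenario_grid,
    run_inversion_scenario, fit_green_fpar_vi,
)

cfg = default_scenario_config("DBF", seed=0)   # synthetic broadleaf forest
grid = run_scenario_grid(cfg)                  # 9 PAI x 7 proportions

half_green = grid[grid.green_proportion == 0.5]
print(half_green[["pai", "fpar_total", "fpar_pav", "fpar_npv", "evi"]]
      .round(4).to_string(index=False))

fit = fit_green_fpar_vi(run_inversion_scenario(cfg), "evi")
print(f"FPAR_PAV = {fit.slope:.2f} x EVI {fit.intercept:+.2f}  "
      f"(r={fit.pearson_r:.3f}, error rate {fit.error_rate_percent:.2f}%)")
```

prints

```
 pai  fpar_total  fpar_pav  fpar_npv    evi
 0.1      0.0623    0.0296    0.0327 0.1339
 0.5      0.2761    0.1397    0.1364 0.1832
 1.0      0.4766    0.2591    0.2174 0.2459
 2.0      0.7242    0.4467    0.2775 0.3572
 3.0      0.8500    0.5825    0.2675 0.4443
 4.0      0.9133    0.6821    0.2312 0.5119
 5.0      0.9450    0.7559    0.1891 0.5649
 6.0      0.9608    0.8109    0.1499 0.6068
 7.0      0.9686    0.8521    0.1165 0.6402
FPAR_PAV = 1.41 x EVI -0.07  (r=0.998, error rate 1.77%)
```

Reading the table: total and green FPAR climb monotonically with plant
area index, while the woody-element FPAR peaks at PAI = 2 — beyond
that, the deepening leaf layer intercepts the beam before it reaches
the branches — so in dense canopies green FPAR approaches total FPAR,
and in open canopies the two diverge strongly.  The fitted line is the
EVI-based inversion model for green FPAR under the deciduous
structure prior (woody area index fixed at 0.5).

The same machinery is exposed on the command line:

```bash
greensail simulate --config run.yaml --out grid.csv
greensail correlate grid.csv
greensail fit grid.csv --vi evi --out fit.json
greensail species                  # per-species green-FPAR table
synth-spectra --kind leaf --profile oak --seed 1 --out oak.csv
```

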