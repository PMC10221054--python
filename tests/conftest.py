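"""Shared fixtures: tiny spectrally-flat optics and cached scenario grids."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import greensail as gs
from greensail.experiments import (
    default_scenario_config,
    run_inversion_scenario,
    run_scenario_grid,
)

#: small wavelength grid covering PAR for closed-form flux tests
WL3 = np.array([500.0, 600.0, 700.0])


def flat_optics(kind: str, rho: float, tau: float = 0.0,
                wl: np.ndarray = WL3, label: str = "flat") -> gs.ComponentOptics:
    """Spectrally flat component optics on a small grid."""
    n = wl.size
    return gs.ComponentOptics(
        kind, label,
        gs.SpectralCurve(wl, np.full(n, float(rho))),
        gs.SpectralCurve(wl, np.full(n, float(tau))),
    )


@pytest.fixture(scope="session")
def geom() -> gs.Geometry:
    """Standard geometry: sun at 30 deg, nadir view, fully direct."""
    return gs.Geometry(30.0, 0.0, 0.0, 1.0)


@pytest.fixture(scope="session")
def dbf_cfg():
    return default_scenario_config("DBF", seed=0)


@pytest.fixture(scope="session")
def enf_cfg():
    return default_scenario_config("ENF", seed=0)


@pytest.fixture(scope="session")
def dbf_grid(dbf_cfg) -> pd.DataFrame:
    return run_scenario_grid(dbf_cfg)


@pytest.fixture(scope="session")
def enf_grid(enf_cfg) -> pd.DataFrame:
    return run_scenario_grid(enf_cfg)


@pytest.fixture(scope="session")
def dbf_inversion(dbf_cfg) -> pd.DataFrame:
    return run_inversion_scenario(dbf_cfg)


@pytest.fixture(scope="session")
def enf_inversion(enf_cfg) -> pd.DataFrame:
    return run_inversion_scenario(enf_cfg)
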