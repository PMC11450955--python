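"""Shared fixtures: phantoms with analytic ground truth and simulated cohorts.

All fixtures are generated programmatically at session scope; nothing is
read from disk except through tmp_path round trips in the tests themselves.
"""

import numpy as np
import pandas as pd
import pytest

import fatomics as f


@pytest.fixture(scope="session")
def sphere_shell_phantom():
    """Concentric spherical sac r=50 mm with a 10 mm EAT shell, 1 mm voxels.

    The canonical geometry oracle: every centroid ray crosses the 40-50 mm
    shell radially, so every thickness measurement should be ~10 mm, and the
    shell volume has the closed form (4pi/3)(50^3 - 40^3).
    """
    spec = f.PhantomSpec(
        shape=(108, 108, 108),
        spacing=(1.0, 1.0, 1.0),
        semi_axes=(50.0, 50.0, 50.0),
        thickness_kind="constant",
        t0=10.0,
        t_amp=0.0,
        hu_loc=-80.0,
        hu_scale=0.0,  # constant -80 HU fat: noiseless threshold oracle
        noise_sd=0.0,
        seed=7,
    )
    vol, sac, truth = f.generate_phantom(spec)
    return vol, sac, truth


@pytest.fixture(scope="session")
def small_phantom():
    """Desk-scale anisotropic ellipsoid phantom with Gaussian EAT HU."""
    spec = f.PhantomSpec(
        shape=(24, 64, 64),
        spacing=(2.5, 2.0, 2.0),
        semi_axes=(25.0, 45.0, 40.0),
        thickness_kind="lobed",
        t0=9.0,
        t_amp=3.0,
        hu_loc=-80.0,
        hu_scale=18.0,
        seed=11,
    )
    vol, sac, truth = f.generate_phantom(spec)
    return vol, sac, truth


@pytest.fixture(scope="session")
def small_phantom_features(small_phantom):
    vol, sac, _ = small_phantom
    return f.extract_all(vol, sac)


@pytest.fixture(scope="session")
def sim_cohort():
    """400-subject simulated cohort: 148 catalog features, 56% events."""
    X = f.simulate_feature_table(400, seed=21)
    spec = f.CohortSpec(
        beta={"EAT_vol": 0.8, "Pro_50_30": 0.7, "Thickness_Kurtosis": 0.6, "Vol_PQ4": 0.5},
        event_fraction=0.56,
        seed=22,
    )
    surv = f.simulate_survival(X, spec)
    return X, surv


def surv_arrays(surv: pd.DataFrame):
    return surv["time_days"].to_numpy(float), surv["event"].to_numpy(int)


@pytest.fixture(scope="session")
def sim_cohort_y(sim_cohort):
    _, surv = sim_cohort
    return surv_arrays(surv)
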