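import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.special import expit

import peakdrift as pk

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth():
    """Frozen diabetes-like expit-polynomial truth."""
    return pk.diabetes_like_truth()


@pytest.fixture(scope="session")
def expected_data(truth):
    """Noise-free aggregated counts at a realistic national cell size."""
    return pk.simulate_counts(truth, totals=400_000, expected=True)


@pytest.fixture(scope="session")
def fitted_model(expected_data):
    return pk.fit(expected_data, deg_a=3, deg_t=1)


def ridge_values(t, a, drift=0.5, center=70.0, t_ref=2000.0, width=50.0, height=2.0):
    """p = expit(height - (a - center - drift*(t - t_ref))^2 / width)."""
    return expit(height - (a - center - drift * (t - t_ref)) ** 2 / width)


@pytest.fixture(scope="session")
def ridge_surface():
    """Shifted-ridge surface with known linear trace a(t) = 70 + 0.5 (t - 2000)."""
    grid = pk.LexisGrid(np.arange(2000.0, 2030.25, 0.25),
                        np.arange(40.0, 100.25, 0.25))
    tt, aa = grid.mesh()
    return pk.PrevalenceSurface(grid, ridge_values(tt, aa), provenance="external")


@pytest.fixture(scope="session")
def invariant_surface():
    """Time-invariant surface: the trace is a constant age."""
    grid = pk.LexisGrid(np.arange(2000.0, 2020.5, 0.5), np.arange(40.0, 100.5, 0.5))
    tt, aa = grid.mesh()
    return pk.PrevalenceSurface(grid, ridge_values(tt, aa, drift=0.0))


@pytest.fixture(scope="session")
def drifting_scenario_surface():
    """PDE solution for the drifting-incidence rate scenario, 2000-2015.

    Solved from 1900 with an empty population so the study window is free
    of cold-start transients, then restricted to t >= 2000.
    """
    rates = pk.make_rate_scenario("drifting_incidence")
    grid = pk.LexisGrid.regular(1900.0, 2015.0, 0.0, 100.0, 0.5, 0.5)
    full = pk.solve_surface(rates, grid, boundary_age=0.0, boundary_time=0.0,
                            substep=0.25)
    keep = grid.t_axis >= 2000.0
    sub = pk.LexisGrid(grid.t_axis[keep], grid.a_axis)
    return pk.PrevalenceSurface(sub, full.values[keep], provenance="pde_solution")
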