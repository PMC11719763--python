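"""Shared fixtures: array geometry, media, phantoms, and precomputed fields.

Expensive artifacts (1 mm phantom, simulated fields) are session-scoped so
the whole suite pays for them once.
"""

import warnings

import numpy as np
import pytest

from lifuplan import build_array
from lifuplan.field_solver import (GridSpec, Medium, scale_to_pnp,
                                   simulate_field, uniform_solution)
from lifuplan.phantom import frontal_sinus_spec, make_head_phantom

NOMINAL = (0.0, 0.0, 50.0)
#: RAS target ~5 cm deep behind the phantom forehead (prefrontal).
PHANTOM_TARGET = (0.0, 40.0, 10.0)


@pytest.fixture(scope="session")
def geom():
    return build_array()


@pytest.fixture(scope="session")
def medium():
    return Medium()


@pytest.fixture(scope="session")
def nominal_field_1mm(geom, medium):
    """1 mm field of the nominal focus, scaled to 820 kPa at the focus."""
    grid = GridSpec.from_bounds((-12.0, -12.0, 30.0), (12.0, 12.0, 66.0), 1.0)
    sol = uniform_solution(geom, NOMINAL)
    field = simulate_field(geom, sol, medium, grid)
    _, sol, field = scale_to_pnp(field, sol, NOMINAL, 820.0)
    return field


@pytest.fixture(scope="session")
def nominal_field_2mm(geom, medium):
    """Coarser nominal-focus field for cheap metric tests."""
    grid = GridSpec.from_bounds((-20.0, -20.0, 20.0), (20.0, 20.0, 70.0), 2.0)
    sol = uniform_solution(geom, NOMINAL)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # > lambda/2 spacing is intentional
        field = simulate_field(geom, sol, medium, grid)
    return field


@pytest.fixture(scope="session")
def phantom_1mm():
    """1 mm head phantom with frontal sinuses, plus its geometric truth."""
    spec = frontal_sinus_spec(sinus_radius_mm=10.0, voxel_size_mm=1.0, seed=3)
    volume, truth = make_head_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def phantom_2mm():
    """Cheap 2 mm phantom for I/O and CLI tests."""
    spec = frontal_sinus_spec(sinus_radius_mm=10.0, voxel_size_mm=2.0, seed=0)
    volume, truth = make_head_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def coarse_steering_map(geom):
    """Steering map on a coarse (5 mm candidate / 2.5 mm field) lattice."""
    from lifuplan.sequence import phase_1_3_plan
    from lifuplan.steering_limits import (candidate_axes, default_field_grid,
                                          map_steering)

    return map_steering(geom, phase_1_3_plan(),
                        candidate_grid=candidate_axes(spacing=5.0),
                        field_grid=default_field_grid(2.5))


def assert_rotation(axes):
    np.testing.assert_allclose(axes.T @ axes, np.eye(3), atol=1e-9)
    assert np.linalg.det(axes) > 0.99
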