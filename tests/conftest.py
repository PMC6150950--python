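import numpy as np
import pytest

from betabeam.config import build_geometry
from betabeam.geometry import (
    EllipsoidSurface,
    HeadModel,
    fit_local_spheres,
    make_helmet_array,
    shrink_surface,
)


@pytest.fixture(scope="session")
def default_geometry():
    """Full 275-channel helmet + default head/source ellipsoids + local spheres."""
    return build_geometry()


@pytest.fixture(scope="session")
def small_geometry():
    """A 40-channel helmet over the same head, for fast pipeline tests."""
    sensors = make_helmet_array(n_channels=40, radius=0.12, coverage=0.5, seed=1)
    head_surface = EllipsoidSurface(center=np.zeros(3), semi_axes=(0.09, 0.07, 0.065))
    source_surface = shrink_surface(head_surface, 0.015)
    head_model = fit_local_spheres(head_surface, sensors, patch_radius=0.04)

    class Geo:
        pass

    geo = Geo()
    geo.sensors = sensors
    geo.head_surface = head_surface
    geo.source_surface = source_surface
    geo.head_model = head_model
    return geo


@pytest.fixture(scope="session")
def sphere_head():
    return HeadModel(mode="single_sphere", sphere_centers=np.zeros((1, 3)), sphere_radii=[0.09])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
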