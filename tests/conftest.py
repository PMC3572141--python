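import numpy as np
import pytest

from megloc import surface as sf
from megloc import forward as fw


@pytest.fixture(scope="session")
def small_cortex():
    """Small two-hemisphere cortex shared by cheap tests."""
    surf = sf.synth_cortex(300, rng_seed=7)
    return surf


@pytest.fixture(scope="session")
def small_adjacency(small_cortex):
    return sf.build_adjacency(small_cortex)


@pytest.fixture(scope="session")
def small_forward(small_cortex):
    sensors = fw.radial_sensor_cap(40, radius_mm=120.0)
    G = fw.spherical_lead_field(sensors, small_cortex, sphere_radius=95.0)
    return sensors, G


@pytest.fixture(scope="session")
def strip_mesh():
    """30-vertex triangle-strip surface (max vertex degree 4)."""
    p = 30
    faces = np.array([[i, i + 1, i + 2] for i in range(p - 2)], dtype=np.int64)
    t = np.linspace(0, 4 * np.pi, p)
    vertices = np.column_stack([7.0 * t, 7.0 * np.sin(t), np.zeros(p)])
    normals = np.tile([0.0, 0.0, 1.0], (p, 1))
    hemisphere = np.array(["left"] * p)
    return sf.TriSurface(vertices, faces, normals, hemisphere)


def random_leadfield(q, p, seed):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(q, p))
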