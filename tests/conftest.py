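import math

import numpy as np
import pytest

import photonmc as pm


class ArrayStream:
    """Deterministic stand-in stream fed from a fixed array of draws.

    Duck-types the SubStream interface the sampling operations consume;
    used both to force specific xi values in hand-worked examples and to
    prefetch real substream draws for tight scalar loops.
    """

    def __init__(self, values):
        self.values = np.asarray(values, dtype=np.float64)
        self.pos = 0

    def uniform(self):
        v = self.values[self.pos]
        self.pos += 1
        return float(v)

    def uniforms(self, n):
        out = self.values[self.pos:self.pos + n]
        self.pos += n
        return np.asarray(out, dtype=np.float64)


@pytest.fixture
def stream():
    return pm.make_substreams(1234, 1)[0]


@pytest.fixture(scope="session")
def homo_fixture():
    """Homogeneous cylinder phantom (matched index, default g)."""
    return pm.make_homogeneous_cylinder_fixture()


@pytest.fixture(scope="session")
def homo_run(homo_fixture):
    """One moderate simulation of the homogeneous phantom, shared by the
    surface-map, profile and conservation checks."""
    scene, src = homo_fixture
    return pm.run_simulation(scene, src, 20_000, seed=7)


@pytest.fixture(scope="session")
def homo_run_reseed(homo_fixture):
    scene, src = homo_fixture
    return pm.run_simulation(scene, src, 20_000, seed=8)


def make_icosphere(radius=10.0, center=(0.0, 0.0, 0.0), subdivisions=3):
    import trimesh
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    v = np.asarray(m.vertices) + np.asarray(center)
    return pm.TriangleMesh(v, np.asarray(m.faces))


def make_meshed_cylinder(radius=15.0, height=30.0, sections=256):
    import trimesh
    m = trimesh.creation.cylinder(radius=radius, height=height,
                                  sections=sections)
    return pm.TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces))
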