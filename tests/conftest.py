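import numpy as np
import pytest
import trimesh

from braintorque import TriMesh, apply_torque, make_brain, TorqueParams


@pytest.fixture(scope="session")
def icosphere() -> TriMesh:
    s = trimesh.creation.icosphere(subdivisions=4)
    return TriMesh(np.asarray(s.vertices), np.asarray(s.faces))


@pytest.fixture(scope="session")
def subdivided_cube() -> TriMesh:
    """Axis-aligned unit cube with face-interior vertices."""
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    box = box.subdivide().subdivide()
    return TriMesh(np.asarray(box.vertices), np.asarray(box.faces))


@pytest.fixture(scope="session")
def symmetric_brain():
    return make_brain(resolution=32)


@pytest.fixture(scope="session")
def torqued_brain(symmetric_brain):
    """A subject with every torque feature injected (no noise, no tilt)."""
    params = TorqueParams(
        petalia_frontal=-0.7, petalia_occipital=-1.6,
        shift_frontal=-0.6, shift_occipital=-1.3,
        bend_frontal=0.5, bend_occipital=3.6,
        delta_length=0.9, delta_height=-0.7, delta_width=0.4,
    )
    return apply_torque(symmetric_brain, params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
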