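import numpy as np
import pytest

from eitdct import adjacent_protocol, build_mesh, make_thorax_scene


def circle_polygon(n=128, radius=1.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return radius * np.column_stack([np.cos(th), np.sin(th)])


@pytest.fixture(scope="session")
def disk_mesh_small():
    """Coarse homogeneous disk (<= 400 elements) for oracle-grade checks."""
    mesh = build_mesh(circle_polygon(), n_elec=16, target_element_count=500)
    assert mesh.n_elems <= 700
    return mesh


@pytest.fixture(scope="session")
def protocol16():
    return adjacent_protocol(16)


@pytest.fixture(scope="session")
def scene128():
    return make_thorax_scene(128, 128, seed=1)


@pytest.fixture(scope="session")
def thorax_inverse_mesh(scene128):
    return build_mesh(scene128.thorax_polygon, 16, 1500)
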