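import numpy as np
import pytest

from ionfem import config as cfgmod
from ionfem.mesh import TriMesh, build_trimesh, generate_ellipse_mesh
from ionfem.stepper import simulate


@pytest.fixture(scope="session")
def unit_triangle() -> TriMesh:
    """Single right triangle (0,0), (1,0), (0,1): every node is a boundary node."""
    return build_trimesh(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]), [[0, 1, 2]])


@pytest.fixture(scope="session")
def disk_mesh() -> TriMesh:
    return generate_ellipse_mesh(1.0, 1.0, 0.2)


@pytest.fixture(scope="session")
def ellipse_mesh_coarse() -> TriMesh:
    return generate_ellipse_mesh(2.0, 1.0, 0.3)


@pytest.fixture(scope="session")
def basic_setup():
    cfg = cfgmod.load_config(cfgmod.bundled_config_path("basic"))
    return cfg, cfgmod.build_setup(cfg)


@pytest.fixture(scope="session")
def basic_run(basic_setup):
    """The full basic enzyme-reaction reference simulation (shared, ~15 s)."""
    cfg, setup = basic_setup
    mesh = cfgmod.build_mesh(cfg)
    traj = simulate(
        mesh, setup.species, setup.kinetics, setup.solver,
        probes=cfg.probes.points, phi0=cfg.phi0,
    )
    return mesh, setup, traj


@pytest.fixture(scope="session")
def suicide_setup():
    cfg = cfgmod.load_config(cfgmod.bundled_config_path("suicide"))
    return cfg, cfgmod.build_setup(cfg)


@pytest.fixture(scope="session")
def suicide_run(suicide_setup):
    """The full suicide-substrate reference simulation (shared, ~2-3 min)."""
    cfg, setup = suicide_setup
    mesh = cfgmod.build_mesh(cfg)
    traj = simulate(
        mesh, setup.species, setup.kinetics, setup.solver,
        probes=cfg.probes.points, phi0=cfg.phi0,
    )
    return mesh, setup, traj
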