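import numpy as np
import pytest

from stagesim import kinematics as kin
from stagesim import staging
from stagesim.arch import build_arch, build_attachments
from stagesim.config import ArchConfig, RunConfig, _default_attachments

# Unit tests run on a deliberately coarse surface sampling; the staging run
# uses the packaged simulation profile (0.8 mm).  Both resolutions leave the
# measured quantities of this model class unchanged (see docs/methods.md).
UNIT_MESH = 1.2


@pytest.fixture(scope="session")
def arch_coarse():
    """Default arch at unit-test resolution, with attachments."""
    arch = build_arch(ArchConfig(mesh_size=UNIT_MESH), seed=0)
    build_attachments(arch, _default_attachments())
    return arch


@pytest.fixture(scope="session")
def bare_arch():
    """Default arch without attachments (geometry-only assertions)."""
    return build_arch(ArchConfig(mesh_size=UNIT_MESH), seed=0)


@pytest.fixture(scope="session")
def sim_config():
    return RunConfig.simulation_profile()


@pytest.fixture(scope="session")
def default_run(sim_config):
    """The full default 20-stage staging simulation (seed 0)."""
    state = staging.initialize_state(sim_config, seed=0)
    for _ in range(sim_config.plan.n_stages):
        staging.run_stage(state)
    return state


@pytest.fixture(scope="session")
def default_kinematics(default_run):
    return kin.trajectory_kinematics(default_run.trajectory)


def random_rigid(rng):
    """Random proper rigid transform (test helper)."""
    from stagesim.transforms import RigidTransform
    rv = rng.normal(size=3)
    return RigidTransform.from_rotvec(rv / np.linalg.norm(rv) * rng.uniform(0.1, 1.5),
                                      rng.normal(scale=5.0, size=3))
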