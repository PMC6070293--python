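import numpy as np
import pytest

from ras1zone.mesh import MeshSpec, build_mesh


@pytest.fixture(scope="session")
def ref_mesh():
    """Reference mating-cell mesh: radius 2 um, tip-to-tip 6 um, 45x40."""
    return build_mesh(MeshSpec(2.0, 6.0, 45, 40))


@pytest.fixture(scope="session")
def coarse_mesh():
    """2x-coarsened mating-cell mesh used for fast model tests."""
    return build_mesh(MeshSpec(2.0, 6.0, 23, 20))


@pytest.fixture(scope="session")
def coarse_interphase_mesh():
    """Coarse interphase-cell mesh (tip-to-tip 11 um) for FRAP fitting."""
    return build_mesh(MeshSpec(2.0, 11.0, 23, 20))


@pytest.fixture(scope="session")
def long_flat_mesh():
    """Long interphase-style mesh whose cylindrical section dominates;
    used for oracle comparisons on the intrinsically flat section."""
    return build_mesh(MeshSpec(2.0, 16.0, 65, 40))


@pytest.fixture(scope="session")
def reference_trajectories(ref_mesh):
    """Three 600-s reference runs shared by the acceptance-level tests."""
    from ras1zone.model import ModelParams, run_simulation

    return {
        seed: run_simulation(ModelParams(), ref_mesh, 600.0, seed=seed)
        for seed in (1, 2, 3)
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
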