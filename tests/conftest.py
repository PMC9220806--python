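import numpy as np
import pytest

from chaintrace import fixtures


@pytest.fixture(scope="session")
def helix_system():
    """30-residue helix simulated at 4 A; the workhorse tracing fixture."""
    return fixtures.make_system(n_res=30, motif="helix", resolution=4.0, seed=1)


@pytest.fixture(scope="session")
def small_system():
    """20-residue helix, for cheap tests."""
    return fixtures.make_system(n_res=20, motif="helix", resolution=4.0, seed=2)


@pytest.fixture(scope="session")
def planted_system():
    """Fine-voxel system with 1 elongated ligand, 5 waters, and one
    half-map-inconsistent blob planted in residual density."""
    base = fixtures.make_system(
        n_res=20,
        motif="helix",
        resolution=3.0,
        voxel_size=0.8,
        seed=5,
        noise_sigma=0.005,
        padding=9.0,
    )
    return fixtures.plant_nonprotein(
        base, ligand_shape="elongated", n_waters=5, inconsistent_blob=True
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
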