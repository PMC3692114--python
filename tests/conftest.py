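import numpy as np
import pytest

from volnma import coarse_grain as cg
from volnma import enm_nma, phantom
from volnma import volume_io as vio


@pytest.fixture(scope="session")
def phantom_pair():
    """Canonical two-domain phantom and its hinge displacement (seed 0)."""
    spec = phantom.PhantomSpec(seed=0)
    model, disp = phantom.make_two_domain_phantom(spec)
    return spec, model, disp


@pytest.fixture(scope="session")
def phantom_volume(phantom_pair):
    spec, model, _ = phantom_pair
    return phantom.structure_to_volume(
        model, spec.grid_dims, spec.voxel_size, spec.resolution
    )


@pytest.fixture(scope="session")
def fitted_phantom(phantom_volume):
    """Masked phantom volume and its fitted pseudo-atom model (σ=2 voxels)."""
    thr = vio.auto_threshold(phantom_volume)
    masked, mask = vio.apply_threshold_mask(phantom_volume, thr)
    model = cg.fit_pseudo_atoms(
        masked, mask,
        cg.FitConfig(sigma_voxels=2.0, target_error=0.06, seed=0),
    )
    return masked, mask, model


@pytest.fixture(scope="session")
def dense_random_network():
    """A well-connected random 50-atom network (6 rigid modes exactly)."""
    rng = np.random.default_rng(7)
    positions = rng.uniform(0.0, 20.0, size=(50, 3))
    return enm_nma.build_network(positions, cutoff=12.0)


@pytest.fixture(scope="session")
def dense_modes(dense_random_network):
    return enm_nma.compute_modes(dense_random_network, n_modes=20)


@pytest.fixture
def small_model():
    rng = np.random.default_rng(3)
    return cg.PseudoAtomModel(
        positions=rng.uniform(5.0, 25.0, size=(40, 3)),
        weights=rng.uniform(0.5, 2.0, size=40),
        sigma=1.5,
        achieved_error=0.042,
        seed=3,
    )
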