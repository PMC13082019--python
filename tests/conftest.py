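import numpy as np
import pytest

from allofit.operational import OperationalParams
from allofit.synthetic import SimConfig, simulate_assay

WT_SURFACE_TRUTH = dict(
    emax=110.0, log_ka=-8.6, log_kb=-6.2, tau_a=5.0, tau_b=0.3,
    log_alpha=1.6, log_beta=0.3, n=1.0,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def wt_params():
    return OperationalParams(**WT_SURFACE_TRUTH)


@pytest.fixture
def noiseless_surface():
    surf, truth = simulate_assay(
        SimConfig(model="operational", truth=WT_SURFACE_TRUTH, noise_sd=0.0, seed=7)
    )
    return surf, truth


def random_rigid_transform(rng):
    """A uniformly random rotation plus a translation, as (R, t)."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    return R, t
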