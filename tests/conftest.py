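import numpy as np
import pytest

from twingxe.params import GeneratingParams, ItemParams, reference_generating_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def classical_params():
    """Classical ACE generating model (no interactions), variances 0.5/0.3/0.2."""
    return GeneratingParams(
        sigma2_A=0.5, gamma0=np.log(0.3), gamma1=0.0,
        beta0=np.log(0.2), beta1=0.0,
        items=tuple(ItemParams(1.0, -0.5, 0.5) for _ in range(6)),
        n_mz=200, n_dz=200, missing_rate=0.0, seed=7)


@pytest.fixture(scope="session")
def reference_params():
    """Published generating truth with the 9-item scale at small family counts."""
    return reference_generating_params(n_mz=150, n_dz=180, seed=11)


@pytest.fixture(scope="session")
def small_dataset(reference_params):
    from twingxe.simulate import simulate_dataset

    return simulate_dataset(reference_params)
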