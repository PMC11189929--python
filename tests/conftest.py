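import numpy as np
import pytest
from hypothesis import settings

import clusterflux as cf

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from clusterflux.synthetic_data import SyntheticConfig


@pytest.fixture(scope="session")
def small_geometry():
    """Moderate three-region geometry used across solver tests."""
    return cf.BasinGeometry(R1=0.5, R2=2.0, R0=4.0)


@pytest.fixture(scope="session")
def small_params():
    """Kinetics with mild screening so all bases stay well conditioned."""
    return cf.KineticParams(
        k=1e-3, D=50.0, alpha0=1.0, beta=0.5, c0_star=100.0, N_total=2e4
    )


@pytest.fixture(scope="session")
def assay_dataset():
    from clusterflux.synthetic_data import gen_llps_assay

    return gen_llps_assay(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def tracer_dataset():
    from clusterflux.synthetic_data import gen_tracer_dataset

    return gen_tracer_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def intensity_dataset():
    from clusterflux.synthetic_data import gen_intensity_table

    return gen_intensity_table(SyntheticConfig(seed=1))


def random_parameterization(rng: np.random.Generator):
    """Draw a random, well-posed (geometry, params, gamma) triple."""
    R1 = rng.uniform(0.1, 1.0)
    R2 = rng.uniform(2.0 * R1, 5.0 * R1 + 1.0)
    R0 = rng.uniform(1.3 * R2, 2.5 * R2)
    geom = cf.BasinGeometry(R1=R1, R2=R2, R0=R0)
    params = cf.KineticParams(
        k=10 ** rng.uniform(-4, -2.5),
        D=10 ** rng.uniform(1, 2.5),
        alpha0=10 ** rng.uniform(-1.5, 0.7),
        beta=10 ** rng.uniform(-1.5, 0.7),
        c0_star=10 ** rng.uniform(1, 2.5),
        N_total=10 ** rng.uniform(2, 5),
    )
    gamma = 10 ** rng.uniform(-1, 2)
    return geom, params, gamma
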