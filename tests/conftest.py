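import numpy as np
import pytest

import repeatscape as rs


@pytest.fixture(scope="session")
def tiny_pair_model():
    """2L=2, q=2 model with hand-set parameters (direct-arithmetic oracle)."""
    h = np.array([[0.5, 0.0], [0.0, 0.3]])
    J = np.zeros((2, 2, 2, 2))
    J[0, 1, 0, 1] = 0.2
    J[1, 0, 1, 0] = 0.2
    lam = np.array([0.1, -0.1])
    return rs.PottsModel(h, J, lam, rs.make_mask_full(2))


@pytest.fixture(scope="session")
def planted_small():
    """Planted 2L=8, q=3 model with couplings and a mild overlap bias."""
    spec = rs.PlantedSpec(L=4, q=3, coupling_density=0.3, seed=42,
                          lambda_profile=np.array([0.0, -0.1, -0.2, -0.3, -0.4]))
    return rs.make_planted_model(spec)


@pytest.fixture(scope="session")
def planted_alignment(planted_small):
    return rs.make_planted_alignment(planted_small, 3000, seed=7)


def random_small_model(rng, L=4, q=3, density=0.25, field_scale=0.5,
                       coupling_scale=0.8, with_lambda=True):
    """A random planted model drawn from an externally provided RNG."""
    seed = int(rng.integers(0, 2**31))
    lam = None
    if with_lambda:
        lam = np.random.default_rng(seed + 1).normal(0.0, 0.3, size=L + 1)
    spec = rs.PlantedSpec(L=L, q=q, coupling_density=density,
                          field_scale=field_scale, coupling_scale=coupling_scale,
                          lambda_profile=lam, seed=seed)
    return rs.make_planted_model(spec)
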