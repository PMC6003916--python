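import numpy as np
import pytest

from tippingmdp import TippingModel


def sample_models(n: int, seed: int, gamma_max: float = 0.999,
                  gamma_one: bool = False) -> list[TippingModel]:
    """Uniformly random model parameter sets for property checks.

    r_h is fixed to 1 so r_l and r_min are the ratios the classification
    depends on.  With ``gamma_one`` the discount factor is pinned at 1.
    """
    rng = np.random.default_rng(seed)
    u = rng.random((n, 5))
    models = []
    for delta, rho, gamma, r_l, r_min in u:
        models.append(TippingModel(
            delta=float(delta), rho=float(rho),
            gamma=1.0 if gamma_one else float(gamma) * gamma_max,
            r_h=1.0, r_l=float(r_l), r_min=float(r_min),
        ))
    return models


@pytest.fixture(scope="session")
def random_models() -> list[TippingModel]:
    return sample_models(300, seed=42)
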