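import numpy as np
import pytest

from anticipation_rl import (
    AnticipationParams,
    BoostSpec,
    FITTED_GROUP_MEANS,
    make_model,
)


@pytest.fixture(scope="session")
def observing_params():
    """Observing-task parameters at the published ratios
    (nu/gamma = 0.5, R = 1, eta0/gamma = 3, c/gamma = 3), taking gamma = 1."""
    return AnticipationParams(
        R=1.0, nu=0.5, gamma=1.0, eta0=3.0, boost=BoostSpec("linear", c=3.0)
    )


@pytest.fixture(scope="session")
def observing_params_noboost():
    return AnticipationParams(R=1.0, nu=0.5, gamma=1.0, eta0=3.0, boost=BoostSpec.none())


@pytest.fixture(scope="session")
def group_mean_params():
    """Group-mean parameters of the full boosted trial-by-trial model."""
    return make_model("boosted_full").params_from_values(dict(FITTED_GROUP_MEANS))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
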