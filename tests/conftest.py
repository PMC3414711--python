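import numpy as np
import pytest

from hydratherm.synthetic import CellConditions, KineticScheme


@pytest.fixture
def warm_conditions() -> CellConditions:
    """Fast-relaxing cell: equilibration time well below the drift time."""
    return CellConditions(
        temperature=400.0,
        water_pressure=0.10,
        drift_time_mean=500.0,
        n_pulses=5000,
    )


@pytest.fixture
def two_step_scheme() -> KineticScheme:
    """max_n = 2 with thermochemistry giving moderate step ratios at 400 K."""
    return KineticScheme(
        max_n=2,
        forward_pseudo_rates=(0.05, 0.05),
        true_thermo=((-64.3, -90.0), (-62.0, -90.0)),
    )


@pytest.fixture
def one_step_scheme() -> KineticScheme:
    return KineticScheme(
        max_n=1,
        forward_pseudo_rates=(0.05,),
        true_thermo=((-64.3, -90.0),),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
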