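import numpy as np
import pytest

from survldm import CountTable, Covariates, SimConfig, SurvivalOutcome


@pytest.fixture
def tiny_table() -> CountTable:
    return CountTable(
        sample_ids=["a", "b", "c"],
        taxon_ids=["t1", "t2", "t3"],
        counts=np.array([[1, 2, 3], [0, 0, 5], [4, 1, 0]]),
    )


@pytest.fixture
def small_outcome() -> SurvivalOutcome:
    rng = np.random.default_rng(7)
    n = 40
    T = rng.exponential(5.0, n)
    C = rng.exponential(8.0, n)
    return SurvivalOutcome(np.minimum(T, C), (T <= C).astype(int))


@pytest.fixture
def small_covariates(small_outcome) -> Covariates:
    rng = np.random.default_rng(8)
    X = np.column_stack([rng.normal(size=small_outcome.n),
                         rng.integers(0, 2, small_outcome.n)])
    return Covariates(X, ["age", "group"]).center()


@pytest.fixture
def sim_config() -> SimConfig:
    return SimConfig(n=50, J=120, n_confounded=60, beta_XZ=0.8, seed=5,
                     censor_rate=0.08)
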