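import pytest

from sasurv.lexicon import load_builtin, load_risk_factor_lexicons
from sasurv.pipeline import run_pipeline
from sasurv.synthetic import SimulationConfig, StratumParams


@pytest.fixture(scope="session")
def en_dict():
    return load_builtin("en")


@pytest.fixture(scope="session")
def fr_dict():
    return load_builtin("fr")


@pytest.fixture(scope="session")
def rf_lexicons_en():
    return load_risk_factor_lexicons("en")


@pytest.fixture(scope="session")
def rf_lexicons_fr():
    return load_risk_factor_lexicons("fr")


def small_config(**overrides) -> SimulationConfig:
    """A fast two-stratum corpus (~2k stays) for mechanics tests."""
    defaults = dict(
        n_hospitals=3,
        strata=[
            StratumParams(sex="female", age_band="8-17", level=8.0,
                          trend=0.05, trend_variation=0.6, sigma=2.0),
            StratumParams(sex="male", age_band="26-65", level=10.0,
                          trend=0.1, trend_variation=0.3, sigma=3.0),
        ],
        background_sa_ratio=1.0,
        seed=123,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_corpus():
    from sasurv.synthetic import generate_cohort
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def demo_result():
    """Full-scale (~50k stays) reference pipeline run, shared by the
    end-to-end tests; generated once per session."""
    return run_pipeline(SimulationConfig(seed=20170801))
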