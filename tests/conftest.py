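import pytest
from hypothesis import HealthCheck, settings

from hyraxnet.nullmodels import PermConfig
from hyraxnet.workflow import (
    build_period_networks,
    fixture_config,
    make_ensemble,
    prepare_study,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study():
    """Fully pre-processed fixture study: 12 individuals, 3 groups, 6 days."""
    return prepare_study(fixture_config(11))


@pytest.fixture(scope="session")
def period_nets(study):
    return build_period_networks(study)


@pytest.fixture(scope="session")
def ensemble(study):
    """100-sample null ensemble on the fixture study."""
    return make_ensemble(study, PermConfig(n_perm=100, seed=99))
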