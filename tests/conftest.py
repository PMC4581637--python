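import pytest
from hypothesis import HealthCheck, settings

from chwcea import DISTRICTS, DecisionModel, load_fixture

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(params=DISTRICTS)
def district(request):
    """Each packaged study district in turn."""
    return load_fixture(request.param)


@pytest.fixture
def shebedino():
    return load_fixture("shebedino")


def make_model(fx) -> DecisionModel:
    return DecisionModel(
        ledger=fx.ledger,
        lives=fx.lives,
        life_table=fx.life_table,
        context=fx.context,
        annualize_startup=fx.annualize_startup,
    )
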