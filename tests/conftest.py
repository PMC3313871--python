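import pytest
from hypothesis import HealthCheck, settings

from helpers import make_table

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def hand_table():
    """Two balanced centers, A:{1,2,3} and B:{4,5,6}; hand-ANOVA oracle."""
    return make_table({"A": [1, 2, 3], "B": [4, 5, 6]})
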