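import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def worked_counts():
    """The reference well: 4000 double, 2000 + 2000 single, 12000 negative.

    Hand-derived values: lambda_total = -ln(0.6) = 0.510826,
    lambda_t1 = lambda_t2 = -ln(0.7) = 0.356675, species probabilities
    p = 1 + ln(0.7)/lambda_total = 0.301769, integrity = 39.646%.
    """
    from ddpcr_integrity import DropletCounts

    return DropletCounts(4000, 2000, 2000, 12000)
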