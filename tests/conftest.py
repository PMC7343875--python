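import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def random_lab(rng, n=1):
    """Random valid Lab triples, broadly spanning the space."""
    from elytra import LabColour

    out = [
        LabColour(
            float(rng.uniform(0, 100)),
            float(rng.uniform(-100, 100)),
            float(rng.uniform(-100, 100)),
        )
        for _ in range(n)
    ]
    return out[0] if n == 1 else out
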