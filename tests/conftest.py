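import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kdiffasm import Sequence, worked_example

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def example():
    """The eight-symbol demonstration instance with derived expectations."""
    return worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(20170)


def random_seq(rng, n, alphabet="ACGT", id="r"):
    return Sequence(id=id, symbols="".join(rng.choice(list(alphabet), size=n)))
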