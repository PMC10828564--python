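import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cgrembed.alignment import RankedRecord
from cgrembed.io import DnaRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_records(rng):
    """Ten random 60-nt records in two groups."""
    return [
        DnaRecord(id=f"s{i}", sequence=random_sequence(rng, 60), group=f"g{i % 2}")
        for i in range(10)
    ]


@pytest.fixture
def ranked_record():
    """A hand-built anchor record with a tie at scores 8, 8."""
    return RankedRecord(
        anchor_id="q",
        neighbors=(("a", 10.0), ("b", 8.0), ("c", 8.0), ("d", 5.0), ("e", 2.0)),
    )
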