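import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

PIXEL_SIZE = 0.325  # µm/px, 20x objective scale used throughout the tests


@pytest.fixture
def pixel_size():
    return PIXEL_SIZE


@pytest.fixture
def random_transcriptome():
    """Two random transcripts (target + decoy), fixed seed."""
    rng = np.random.default_rng(1234)
    bases = list("ACGT")
    return {
        "HER2": "".join(rng.choice(bases, size=2000)),
        "DECOY": "".join(rng.choice(bases, size=8000)),
    }
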