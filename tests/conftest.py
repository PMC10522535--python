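import numpy as np
import pytest

from somatoprf.grid import GridSpec, build_tw_sequence, concatenate_sequences
from somatoprf.models import HRFParams


@pytest.fixture(scope="session")
def grid():
    return GridSpec()


@pytest.fixture(scope="session")
def hrf():
    return HRFParams()


@pytest.fixture(scope="session")
def session_seq():
    """Study-layout session: BD fwd+rev, WD 2x(fwd+rev), diagonal fwd."""
    runs = [
        ("between", "forward"),
        ("between", "reverse"),
        ("within", "forward"),
        ("within", "reverse"),
        ("within", "forward"),
        ("within", "reverse"),
        ("diagonal", "forward"),
    ]
    return concatenate_sequences([build_tw_sequence(p, d) for p, d in runs])


@pytest.fixture(scope="session")
def short_seq():
    """One forward run of each paradigm (faster fitting in unit tests)."""
    return concatenate_sequences(
        [build_tw_sequence(p, "forward") for p in ("between", "within", "diagonal")]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
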