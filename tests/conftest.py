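import numpy as np
import pytest

from scalobeat.synthetic import SynthSpec, generate_database, generate_record


@pytest.fixture(scope="session")
def synth_db():
    """Five synthetic patients, 60 s each: three train + two test."""
    return generate_database(5, SynthSpec(duration=60.0), seed=1)


@pytest.fixture(scope="session")
def short_record():
    """One 20 s synthetic record with all three beat classes."""
    return generate_record(SynthSpec(record_id="s900", duration=20.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
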