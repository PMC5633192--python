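import numpy as np
import pytest

from welanopt.datasets import load_printed_normalized, load_printed_records


@pytest.fixture(scope="session")
def printed_raw():
    """The 25 published fermentation records, raw units."""
    return load_printed_records()


@pytest.fixture(scope="session")
def printed_normalized():
    """The same records as published after min-max normalization."""
    return load_printed_normalized()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
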