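import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from strwga.synthetic_data import make_synthetic_panel


@pytest.fixture(scope="session")
def tiny_panel():
    """Six-locus synthetic panel with its reference chromosome."""
    return make_synthetic_panel(6, seed=11)


@pytest.fixture(scope="session")
def medium_panel():
    """200-locus AC-dominated panel used by simulation tests."""
    return make_synthetic_panel(200, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
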