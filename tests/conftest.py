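import numpy as np
import pytest

import ecgdelin as e
from ecgdelin import nn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def specs():
    return e.default_specs()


@pytest.fixture
def nsr_record(specs):
    return e.synthesize_record(specs["NSR"], 10, 500, rng_seed=7, record_id="nsr0")


@pytest.fixture
def float64_engine():
    """Run the autodiff engine in float64 (for finite-difference checks)."""
    nn.set_default_dtype(np.float64)
    yield
    nn.set_default_dtype(np.float32)


def label_array_from_runs(runs):
    """Expand a [(label, length), ...] spec into a label array."""
    out = []
    for label, length in runs:
        out.extend([label] * length)
    return np.array(out, dtype=np.int8)
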