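import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def float64_engine(monkeypatch):
    """Run the nn engine in double precision for finite-difference checks."""
    from folliseg import nn
    monkeypatch.setattr(nn, "DTYPE", np.float64)
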