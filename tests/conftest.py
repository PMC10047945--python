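import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mventropy import MultichannelSeries, gen_wgn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)


@pytest.fixture()
def wgn_pair():
    """Short two-channel white-noise series for estimator unit tests."""
    return gen_wgn(2, 300, 7)


@pytest.fixture()
def tri_series():
    """Three-channel deterministic-ish series with distinct channels."""
    rng = np.random.default_rng(11)
    base = np.vstack(
        [
            np.sin(np.linspace(0, 20, 400)) + 0.1 * rng.standard_normal(400),
            rng.standard_normal(400),
            np.cumsum(rng.standard_normal(400)) / 10.0,
        ]
    )
    return MultichannelSeries(base, label="tri")
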