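import numpy as np
import pytest

from bcgomp.core import Recording
from bcgomp.montage import spherical_cap_montage
from bcgomp.simulate import BcgSimConfig, simulate_bcg


@pytest.fixture(scope="session")
def montage256():
    return spherical_cap_montage(256)


@pytest.fixture(scope="session")
def bcg_session():
    """30 s, 16-channel artifact-only session with full generator output."""
    cfg = BcgSimConfig(C=16, T=250 * 30, seed=42)
    rec, beats, mixing, sources = simulate_bcg(cfg)
    return {"cfg": cfg, "rec": rec, "beats": beats, "mixing": mixing,
            "sources": sources}


@pytest.fixture
def random_recording():
    rng = np.random.default_rng(7)
    return Recording(data=rng.standard_normal((6, 40)), fs=250.0)
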