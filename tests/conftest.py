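import matplotlib

matplotlib.use("Agg")

import pytest
from hypothesis import settings

import ppptrace as pt

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lactate_fragment():
    """The diagnostic lactate C2-C3 fragment ion (m/z 117)."""
    return pt.DEFAULT_FRAGMENTS["lactate_117"]


@pytest.fixture(scope="session")
def lactate_full_ion():
    """The full-backbone lactate [M-CH3]+ ion."""
    return pt.DEFAULT_FRAGMENTS["lactate_full"]


@pytest.fixture(scope="session")
def pyruvate_full_ion():
    return pt.DEFAULT_FRAGMENTS["pyruvate_full"]


@pytest.fixture(scope="session")
def pure_tracer():
    return pt.TracerSpec(purity=1.0, nat_abund_13c=0.0)
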