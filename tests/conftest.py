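"""Shared fixtures.

The forward acoustic simulation is the expensive stage (~15 s per run), so
the s4 pipeline runs once per session, paired with its blood-only twin,
and every test that needs a realistic reconstruction reuses it.
"""

import numpy as np
import pytest

from cavipact import evaluate as ev


@pytest.fixture(scope="session")
def s4_paired():
    """Paired uniform-light s4 simulations with isolated artifact."""
    return ev.paired_artifact_case("s4")


@pytest.fixture(scope="session")
def s4_case(s4_paired):
    """The full (blood + air + water) uniform-light s4 pipeline products."""
    return s4_paired["full"]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
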