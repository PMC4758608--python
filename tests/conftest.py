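"""Shared fixtures: small synthetic sessions and deterministic RNGs."""

from __future__ import annotations

import numpy as np
import pytest

from thetawhisk.synthetic import SimConfig, gen_session


@pytest.fixture(scope="session")
def small_session():
    """A 40-trial session with default parameters (seed 123)."""
    return gen_session(SimConfig(n_trials=40, seed=123))


@pytest.fixture(scope="session")
def small_session_phases(small_session):
    from thetawhisk.pipeline import session_phases

    return session_phases(small_session)


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
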