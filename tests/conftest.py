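"""Shared fixtures.  The expensive protocol runs are session-scoped so the
whole suite costs a handful of ODE integrations, not one per test."""

import numpy as np
import pytest

from abagrn import build_model, equilibrate, run_aba_protocol


@pytest.fixture(scope="session")
def model():
    return build_model()


@pytest.fixture(scope="session")
def pre_state(model):
    """Quasi-steady state of the full default model at ABA = 0."""
    return equilibrate(model).state


@pytest.fixture(scope="session")
def wt_traj(model, pre_state):
    """Wild-type 100 uM ABA step response (the reference trajectory)."""
    return run_aba_protocol(model, 100.0, pre_state=pre_state)


@pytest.fixture(scope="session")
def nofb_eq(model):
    """Equilibration with all ABRE-feedback transcription disabled."""
    return equilibrate(model.with_parameters({"kf26": 0.0}))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
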