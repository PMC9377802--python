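"""Shared fixtures.

Long simulations are session-scoped so that the reference seizure run, the
noise-free run and the probe protocol are executed once and shared by every
test that inspects them.
"""

from __future__ import annotations

import numpy as np
import pytest

from slenet import build_network
from slenet.network import RunSpec
from slenet.engine import integrate
from slenet.protocols import (run_noise_free_sle, run_reference_sle,
                              settled_state)


@pytest.fixture(scope="session")
def model():
    return build_network()


@pytest.fixture(scope="session")
def settled(model):
    return settled_state(model)


@pytest.fixture(scope="session")
def reference_traces(model, settled):
    """One 240 s reference seizure-like-event run (seed 1)."""
    return run_reference_sle(model, seed=1, state=settled)


@pytest.fixture(scope="session")
def reference_traces_multi(model, settled, reference_traces):
    """Reference runs for seeds 1-5 (seed 1 reused from the shared run)."""
    runs = {1: reference_traces}
    for seed in (2, 3, 4, 5):
        runs[seed] = run_reference_sle(model, seed=seed, state=settled)
    return runs


@pytest.fixture(scope="session")
def noise_free_traces(model, settled):
    """Deterministic (DC-compensated) seizure run for the IBI analyses."""
    return run_noise_free_sle(model, state=settled)


@pytest.fixture(scope="session")
def rest_60s(model, settled):
    """60 s input-free run from the settled state."""
    traces, state = integrate(model, RunSpec(duration=60e3, poisson=False),
                              state=settled)
    return traces, state
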