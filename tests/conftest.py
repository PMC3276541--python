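"""Shared fixtures: small networks and cached simulation runs.

Expensive simulations are module- or session-scoped so that several tests
can interrogate one run. All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

from ping_assembly import network_builder as nb
from ping_assembly.simulator import run_simulation


@pytest.fixture(scope="session")
def strong_ping_run():
    """A locked strong-PING run of a mid-sized homogeneous network."""
    net = nb.build_all_to_all(80, 20, gbar_ei=0.25, gbar_ie=0.2, gbar_ii=0.1)
    drives = nb.DriveSpec(drive_e=np.full(80, 1.6), drive_i=np.zeros(20))
    return run_simulation(net, drives, duration=300.0, dt=0.02, seed=7)


@pytest.fixture(scope="session")
def small_net():
    net = nb.build_all_to_all(10, 4, gbar_ei=0.2, gbar_ie=0.2, gbar_ii=0.1)
    drives = nb.DriveSpec(drive_e=np.full(10, 1.5), drive_i=np.zeros(4))
    return net, drives


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
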