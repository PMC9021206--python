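import numpy as np
import pytest

from supramol import models, synthetic
from supramol.clustering import MembershipTrajectory


@pytest.fixture(scope="session")
def m_topology():
    return models.build_monomer("M")


@pytest.fixture(scope="session")
def bta_topology():
    return models.build_monomer("BTA")


@pytest.fixture(scope="session")
def kmc_stationary():
    """Long, finely sampled aggregation-fragmentation trajectory.

    Sampling (0.02 time units) is much shorter than the mean inter-event
    time, so almost every sampling interval contains at most one event and
    the binary-event assumption of the transition-matrix analysis holds.
    The first 100 time units are discarded as equilibration.
    """
    params = synthetic.KMCParams(
        n_monomers=200, k_merge=0.02, k_frag=0.05,
        t_end=1000.0, sample_dt=0.02, seed=42,
    )
    membership, event_log = synthetic.run_kmc(params)
    burn = 5000  # 100 time units
    stationary = MembershipTrajectory(membership.frames[burn:])
    return membership, stationary, event_log, params


@pytest.fixture(scope="session")
def kmc_events_in_window(kmc_stationary):
    """Event log restricted to the stationary window."""
    _, stationary, event_log, _ = kmc_stationary
    t0 = stationary.frames[0].frame_time
    t1 = stationary.frames[-1].frame_time
    sub = synthetic.EventLog()
    for t, kind, p1, p2, res in zip(
        event_log.times, event_log.kinds, event_log.p1,
        event_log.p2, event_log.result,
    ):
        if t0 < t <= t1:
            sub.add(t, kind, p1, p2, res)
    return sub


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
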