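import numpy as np
import pytest

from igh_elastica.mechanics import (
    PullingProtocol,
    myomesin_arm,
    myomesin_chain,
    simulate_pull,
)


@pytest.fixture(scope="session")
def fast_pulls():
    """Ten fast (1 um/s) pulls of the dimer chain with 3 pN force noise."""
    chain = myomesin_chain()
    traces = []
    for seed in range(10):
        prot = PullingProtocol.constant_velocity(420.0, 1000.0, seed=seed)
        traces.append(simulate_pull(chain, prot))
    return traces


@pytest.fixture(scope="session")
def slow_pulls():
    """Six slow (10 nm/s) pulls of one monomer arm (4 helical linkers)."""
    arm = myomesin_arm()
    traces = []
    for seed in range(6):
        prot = PullingProtocol.constant_velocity(48.0, 10.0, seed=seed)
        traces.append(simulate_pull(arm, prot))
    return traces


@pytest.fixture(scope="session")
def stretch_relax_cycles():
    """Six stretch-relax cycles at 10 nm/s, split into the two phases."""
    arm = myomesin_arm()
    cycles = []
    for seed in range(6):
        prot = PullingProtocol.stretch_relax(48.0, 10.0, seed=seed)
        trace = simulate_pull(arm, prot)
        n = len(trace) // 2
        cycles.append((_slice(trace, 0, n), _slice(trace, n, len(trace))))
    return cycles


def _slice(trace, lo, hi):
    from igh_elastica.mechanics import ForceExtensionTrace

    return ForceExtensionTrace(
        time=trace.time[lo:hi],
        stage_position=trace.stage_position[lo:hi],
        molecular_extension=trace.molecular_extension[lo:hi],
        force=trace.force[lo:hi],
        events=[e for e in trace.events if trace.time[lo] <= e[0] <= trace.time[hi - 1]],
        metadata=trace.metadata,
    )


@pytest.fixture(scope="session")
def superhelix():
    from igh_elastica.geometry import build_synthetic_superhelix

    return build_synthetic_superhelix(10, seed=0)
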