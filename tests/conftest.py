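import numpy as np
import pytest

import emtpdl1 as ep


@pytest.fixture(scope="session")
def core_network():
    return ep.builtin_network("core_emt_pdl1")


@pytest.fixture(scope="session")
def small_core_ensemble(core_network):
    """A cheap core-network ensemble for unit-level checks."""
    cfg = ep.EnsembleConfig(num_models=300, num_initial_conditions=50, seed=42)
    return ep.run_ensemble(core_network, config=cfg)


@pytest.fixture(scope="session")
def toggle_network():
    """Symmetric two-node toggle switch (A -| B, B -| A)."""
    from emtpdl1.networks import INHIBITION, NetworkTopology, RegulatoryEdge

    return NetworkTopology(
        "toggle",
        ("A", "B"),
        (RegulatoryEdge("A", "B", INHIBITION), RegulatoryEdge("B", "A", INHIBITION)),
    )


@pytest.fixture(scope="session")
def single_node_network():
    """One self-regulating node with a neutral (lam=1) loop.

    A lone unregulated node cannot be expressed as a topology (at least
    one edge is required), so the self-loop is disabled through its
    fold change when parameters are constructed.
    """
    from emtpdl1.networks import ACTIVATION, NetworkTopology, RegulatoryEdge

    return NetworkTopology("solo", ("A",), (RegulatoryEdge("A", "A", ACTIVATION),))


def make_params(topology, g, k, lam, hill_n, x0):
    """Convenience constructor for explicit kinetic parameter sets."""
    return ep.KineticParameterSet(
        topology=topology,
        g=np.asarray(g, dtype=float),
        k=np.asarray(k, dtype=float),
        lam=np.asarray(lam, dtype=float),
        hill_n=np.asarray(hill_n, dtype=np.int64),
        x0=np.asarray(x0, dtype=float),
    )
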