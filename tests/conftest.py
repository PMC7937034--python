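import logging

import numpy as np
import pytest

import funlink as fl

# evidence-feature warnings about genes absent from a table are expected
# all over the synthetic fixtures; keep test output readable
logging.getLogger("funlink.evidence").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_bundle() -> fl.FixtureBundle:
    """A compact planted-module bundle shared by read-only tests."""
    cfg = fl.FixtureConfig(
        n_genes=120,
        n_modules=4,
        module_size_range=(20, 40),
        p_edge_within=0.3,
        p_edge_between=0.005,
        n_gold=40,
        seed=11,
    )
    return fl.generate(cfg)


@pytest.fixture()
def path_net() -> fl.Interactome:
    net = fl.Interactome()
    net.add_edge("g1", "g2")
    net.add_edge("g2", "g3")
    net.add_edge("g3", "g4")
    return net


@pytest.fixture()
def er_net() -> fl.Interactome:
    """Erdos-Renyi graph with ~200 edges for degree/rewiring checks."""
    rng = np.random.default_rng(42)
    genes = [f"n{i:03d}" for i in range(60)]
    net = fl.Interactome(genes=genes)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if rng.random() < 0.115:
                net.add_edge(genes[i], genes[j])
    return net
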