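import pytest

from tfnet import GeneratorConfig, RegulatoryNetwork, SignedInteraction, generate


def build_net(edges, aggregation="signed-max"):
    """Helper: network from (source, target, weight) triples."""
    net = RegulatoryNetwork(aggregation=aggregation)
    for s, t, w in edges:
        net.add_interaction(SignedInteraction(source=s, target=t, weight=w))
    return net


@pytest.fixture
def triangle_net():
    """A -> B, A -> C, B -> C: degrees A (0,2), B (1,1), C (2,0)."""
    return build_net([("A", "B", 1.0), ("A", "C", 2.0), ("B", "C", -1.0)])


@pytest.fixture
def star_net():
    """One hub TF regulating 8 effectors (an unregulated master)."""
    return build_net([("TF", f"g{i}", 1.0) for i in range(1, 9)])


@pytest.fixture
def small_instance():
    """A seeded synthetic instance shared across tests."""
    cfg = GeneratorConfig(n_master=3, n_tf=10, n_effector=50, seed=7)
    records, manifest = generate(cfg)
    return cfg, records, manifest
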