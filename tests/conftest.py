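import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20210423)


def random_graph(rng, n_min=4, n_max=30, p=None):
    """A random (possibly disconnected) labelled graph."""
    n = int(rng.integers(n_min, n_max + 1))
    p = p if p is not None else float(rng.uniform(0.1, 0.6))
    G = nx.Graph()
    names = [f"N{i:02d}" for i in range(n)]
    G.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                G.add_edge(names[i], names[j])
    return G


@pytest.fixture
def small_dataset():
    """A small synthetic dataset shared by pipeline-level tests."""
    from dupnet.synthetic import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(n_nodes=400, attachment=4, genes_per_region=8,
                          disease_module_size=15, n_causal_seeds=5,
                          n_terms=15, term_size=10, extra_association_rows=60)
    return generate_dataset(cfg, seed=7)
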