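import numpy as np
import pandas as pd
import pytest

import netstrat as ns


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong-signal planted cohort at the default study conditions."""
    return ns.generate_cohort(ns.SimConfig(seed=0))


@pytest.fixture(scope="session")
def strong_smoothed(strong_cohort):
    """Aligned binary matrix, network, and quantile-normalized smoothed profile."""
    aligned, net, report = ns.align_to_network(
        strong_cohort.gene_matrix, strong_cohort.network
    )
    profile = ns.smooth_profiles(aligned, net)
    return aligned, net, profile


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort (3 subgroups, 20 samples each) for the slower stages."""
    cfg = ns.SimConfig(
        n_modules=3, module_size=15, n_background_genes=40,
        k_true=3, samples_per_subgroup=20, seed=11,
    )
    return ns.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_smoothed(small_cohort):
    aligned, net, _ = ns.align_to_network(small_cohort.gene_matrix, small_cohort.network)
    profile = ns.smooth_profiles(aligned, net)
    return aligned, net, profile


def random_graph_matrix(rng, n_nodes, n_samples, p_edge=0.15):
    """Random connected graph (path + random edges) and a random binary profile."""
    import networkx as nx

    graph = nx.Graph()
    nodes = [f"n{i}" for i in range(n_nodes)]
    for u, v in zip(nodes, nodes[1:]):
        graph.add_edge(u, v, weight=1.0)
    for i in range(n_nodes):
        for j in range(i + 2, n_nodes):
            if rng.random() < p_edge:
                graph.add_edge(nodes[i], nodes[j], weight=float(rng.integers(1, 4)))
    F0 = pd.DataFrame(
        (rng.random((n_samples, n_nodes)) < 0.2).astype(float),
        index=[f"s{i}" for i in range(n_samples)],
        columns=nodes,
    )
    return graph, F0
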