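"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest

from stagenet.community import Partition, modularity
from stagenet.networks import Network, _key
from stagenet.simulate import SimulationConfig, generate_dataset


# ---------------------------------------------------------------------------
# graph helpers


def make_network(edge_list, weighted=True, stage="test", r_th=0.0) -> Network:
    """Network from [(a, b) or (a, b, w), ...]."""
    edges = {}
    nodes = set()
    for e in edge_list:
        a, b = e[0], e[1]
        w = float(e[2]) if len(e) > 2 else 1.0
        edges[_key(str(a), str(b))] = w
        nodes.update((str(a), str(b)))
    return Network(stage=stage, nodes=nodes, edges=edges, r_th=r_th, weighted=weighted)


def random_gnm_network(n_nodes: int, n_edges: int, rng) -> Network:
    nodes = [f"n{i:03d}" for i in range(n_nodes)]
    edges = {}
    while len(edges) < n_edges:
        a, b = rng.choice(n_nodes, size=2, replace=False)
        edges[_key(nodes[int(a)], nodes[int(b)])] = 1.0
    return Network("rand", set(nodes), edges, 0.0, False)


# ---------------------------------------------------------------------------
# oracles


def set_partitions(items):
    """All set partitions via restricted growth strings."""
    items = list(items)
    n = len(items)
    if n == 0:
        yield {}
        return
    rgs = [0] * n
    maxima = [0] * n
    while True:
        yield {items[i]: rgs[i] for i in range(n)}
        # next restricted growth string
        i = n - 1
        while i > 0 and rgs[i] == maxima[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        rgs[i] += 1
        m = max(maxima[i - 1], rgs[i])
        for j in range(i + 1, n):
            rgs[j] = 0
            maxima[j] = m
        maxima[i] = m


def exhaustive_best_partition(network: Network) -> tuple[dict, float]:
    """Brute-force modularity maximization over all node partitions."""
    nodes = sorted(network.edge_bearing_nodes())
    best, best_q = None, -np.inf
    for assignment in set_partitions(nodes):
        q = modularity(network, assignment)
        if q > best_q:
            best, best_q = dict(assignment), q
    return best, best_q


def exact_hypergeom_tail(n_pop: int, m_succ: int, n_draw: int, k: int) -> float:
    """P[X >= k] by exact rational arithmetic (independent of scipy)."""
    if k <= 0:
        return 1.0
    total = comb(n_pop, n_draw)
    acc = Fraction(0)
    for i in range(k, min(m_succ, n_draw) + 1):
        acc += Fraction(comb(m_succ, i) * comb(n_pop - m_succ, n_draw - i), total)
    return float(acc)


def enumerate_edge_subsets_tail(d: int, set_genes: set, n: int, k: int) -> float:
    """Literal enumeration oracle: fraction of n-edge subsets of the complete
    graph on d genes carrying >= k edges internal to ``set_genes``."""
    genes = [f"g{i}" for i in range(d)]
    inset = {g for g in genes if g in set_genes}
    pairs = list(combinations(genes, 2))
    hits = 0
    total = 0
    for subset in combinations(pairs, n):
        total += 1
        internal = sum(1 for a, b in subset if a in inset and b in inset)
        if internal >= k:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# datasets


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=120,
        n_blocks=3,
        genes_per_block=25,
        block_rho=0.9,
        de_fraction=0.1,
        de_effect=2.0,
        noise_sd=0.5,
        n_outliers=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def gene_matrix(small_dataset):
    from stagenet.io import collapse_probes

    return collapse_probes(small_dataset.expression, small_dataset.gene_of)


def planted_partition(truth_blocks: dict[str, int], nodes) -> Partition:
    keep = set(nodes)
    return Partition({g: b for g, b in truth_blocks.items() if g in keep}, 0.0)
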