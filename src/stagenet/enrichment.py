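"""Edge-based and gene-based hypergeometric enrichment of gene sets.

The edge-based test asks whether a network places more of its ``n`` edges
inside a gene set than expected if the edges were drawn uniformly from all
``N = d(d-1)/2`` pairs of the ``d`` master-list genes. With ``d_set``
genes of the set in the master list, ``m_set = d_set(d_set-1)/2`` pairs
are internal to the set, and the p-value is the upper hypergeometric tail
P[X >= k] with population ``N``, successes ``m_set`` and draws ``n``
(in R terms: ``phyper(k-1, n, N-n, m_set, lower.tail=FALSE)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .networks import Network

__all__ = [
    "EnrichmentQuery",
    "edge_enrichment_pvalue",
    "count_set_edges",
    "enrich_networks",
    "gene_enrichment_pvalue",
    "enrich_network_genes",
]


@dataclass(frozen=True)
class EnrichmentQuery:
    """Hypergeometric edge-enrichment inputs derived from (d, d_set)."""

    d: int        # master-list gene count
    d_set: int    # set genes present in the master list
    n: int        # observed network edge count
    k: int        # observed edges internal to the set

    @property
    def n_pairs(self) -> int:
        return self.d * (self.d - 1) // 2

    @property
    def m_set(self) -> int:
        return self.d_set * (self.d_set - 1) // 2

    def validate(self) -> None:
        if min(self.d, self.d_set, self.n, self.k) < 0:
            raise ValueError("all counts must be >= 0")
        if self.d_set > self.d:
            raise ValueError("d_set cannot exceed d")
        if self.n > self.n_pairs:
            raise ValueError("n cannot exceed d(d-1)/2")
        if self.k > min(self.n, self.m_set):
            raise ValueError("k cannot exceed min(n, m_set)")


def edge_enrichment_pvalue(query: EnrichmentQuery) -> float:
    """Upper-tail hypergeometric P[X >= k]; 1 when k = 0."""
    query.validate()
    if query.k == 0:
        return 1.0
    # survival function is P[X > k-1] = P[X >= k]
    p = float(hypergeom.sf(query.k - 1, query.n_pairs, query.m_set, query.n))
    return min(1.0, max(p, float(np.finfo(float).tiny)))


def count_set_edges(network: Network, gene_set, master) -> tuple[int, int]:
    """(d_set, k): set genes in the master list, and network edges internal
    to that intersection."""
    inset = set(gene_set) & set(master)
    k = sum(1 for a, b in network.edges if a in inset and b in inset)
    return len(inset), k


def enrich_networks(
    networks,
    sets: dict[str, set[str]],
    master,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Edge-based enrichment of every set on every network.

    Returns one row per (network, set) with BH q-values within network,
    sorted by network label then p-value.
    """
    master = set(master)
    d = len(master)
    frames = []
    for net in networks:
        rows = []
        for name, members in sets.items():
            d_set, k = count_set_edges(net, members, master)
            q = EnrichmentQuery(d=d, d_set=d_set, n=net.n_edges, k=k)
            rows.append((net.stage, name, d_set, k, edge_enrichment_pvalue(q)))
        df = pd.DataFrame(
            rows, columns=["network", "set", "d_set", "k", "p_value"]
        )
        df["q_value"] = (
            multipletests(df["p_value"], method="fdr_bh")[1] if len(df) else []
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["network", "set", "d_set", "k", "p_value", "q_value"]
    )
    out["significant"] = out["p_value"] <= alpha
    return out.sort_values(["network", "p_value"], kind="mergesort").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# gene-based (node) enrichment — secondary utility


def gene_enrichment_pvalue(d: int, d_set: int, n_nodes: int, k_nodes: int) -> float:
    """Node-level hypergeometric tail: population d, successes d_set,
    draws n_nodes, observed k_nodes set genes among the network's nodes.
    An in-house approximation of classical over-representation analysis,
    not of any specific web tool's modified score."""
    if k_nodes == 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(k_nodes - 1, d, d_set, n_nodes)))


def enrich_network_genes(
    networks, sets: dict[str, set[str]], master, alpha: float = 0.05
) -> pd.DataFrame:
    master = set(master)
    d = len(master)
    rows = []
    for net in networks:
        nodes = net.edge_bearing_nodes() & master
        for name, members in sets.items():
            d_set = len(set(members) & master)
            k_nodes = len(set(members) & nodes)
            rows.append(
                (
                    net.stage,
                    name,
                    d_set,
                    k_nodes,
                    gene_enrichment_pvalue(d, d_set, len(nodes), k_nodes),
                )
            )
    out = pd.DataFrame(
        rows, columns=["network", "set", "d_set", "k_nodes", "p_value"]
    )
    out["significant"] = out["p_value"] <= alpha
    return out.sort_values(["network", "p_value"], kind="mergesort").reset_index(
        drop=True
    )
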