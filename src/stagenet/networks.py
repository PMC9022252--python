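"""Stage-specific correlation networks with analytically calibrated cutoffs.

An edge joins two genes when the two-sided p-value of their Pearson
correlation, under the exact t transform with ``df = n_samples - 2``,
is at or below ``p_edge`` — equivalently when ``|r| >= critical_r(n, p)``.
Weighted networks carry ``|r|`` as edge weight; unweighted carry 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ScoredEdgeList

__all__ = [
    "Network",
    "critical_r",
    "build_stage_network",
    "stage_unique_network",
    "gene_weights",
    "extract_key_subnetwork",
]

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


def _key(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass
class Network:
    """Undirected weighted gene network stored as a sorted-pair edge dict."""

    stage: str
    nodes: set[str]
    edges: dict[Edge, float]
    r_th: float
    weighted: bool = True

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a > b:
                raise ValueError(f"edge key {(a, b)} not sorted")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        return sum(node in e for e in self.edges)

    def edge_bearing_nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def induced_subgraph(self, keep) -> "Network":
        keep = set(keep)
        return Network(
            stage=self.stage,
            nodes=self.nodes & keep,
            edges={e: w for e, w in self.edges.items()
                   if e[0] in keep and e[1] in keep},
            r_th=self.r_th,
            weighted=self.weighted,
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(stage=self.stage, r_th=self.r_th, weighted=self.weighted)
        g.add_nodes_from(sorted(self.nodes))
        for (a, b), w in sorted(self.edges.items()):
            g.add_edge(a, b, weight=float(w))
        return g

    def write_tsv(self, path) -> None:
        rows = sorted(self.edges.items())
        pd.DataFrame(
            {
                "gene_a": [e[0] for e, _ in rows],
                "gene_b": [e[1] for e, _ in rows],
                "weight": [w for _, w in rows],
            }
        ).to_csv(path, sep="\t", index=False)

    def write_graphml(self, path, node_log2fc: dict[str, float] | None = None) -> None:
        g = self.to_networkx()
        if node_log2fc:
            for n in g.nodes:
                if n in node_log2fc:
                    g.nodes[n]["log2fc"] = float(node_log2fc[n])
        nx.write_graphml(g, path)


def critical_r(n_samples: int, p: float = 0.001) -> float:
    """Correlation magnitude whose two-sided test p-value equals ``p``.

    Inverts the Pearson test statistic ``t = r * sqrt(df) / sqrt(1 - r^2)``
    with ``df = n_samples - 2``: ``r = t_q / sqrt(df + t_q^2)`` where
    ``t_q`` is the upper ``p/2`` quantile of Student's t. Strictly
    decreasing in ``n_samples``; returns 0 when ``p = 1``.
    """
    if n_samples < 3:
        raise ValueError("critical_r needs n_samples >= 3")
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    df = n_samples - 2
    t_q = stats.t.isf(p / 2.0, df)
    return float(t_q / np.sqrt(df + t_q * t_q))


def build_stage_network(
    matrix: pd.DataFrame,
    stage: str = "",
    p: float = 0.001,
    weighted: bool = True,
    block_size: int = 512,
) -> Network:
    """Threshold all pairwise Pearson correlations of one stage's samples.

    ``matrix`` is gene x sample, restricted to the master DEG list and to
    the samples of one stage. Correlations are computed in column blocks so
    the full gene x gene matrix is never materialized. Genes constant
    within the stage are excluded from this network (logged).
    """
    n = matrix.shape[1]
    if n < 3:
        raise ValueError("build_stage_network needs >= 3 samples")
    if matrix.shape[0] < 2:
        raise ValueError("build_stage_network needs >= 2 genes")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    constant = sd == 0.0
    if constant.any():
        logger.warning(
            "excluding %d zero-variance gene(s) from stage %r network",
            int(constant.sum()), stage,
        )
    keep_idx = np.flatnonzero(~constant)
    genes = matrix.index.to_numpy()[keep_idx]
    z = x[keep_idx]
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
    r_th = critical_r(n, p)
    edges: dict[Edge, float] = {}
    d = len(genes)
    denom = n - 1
    for i0 in range(0, d, block_size):
        zi = z[i0:i0 + block_size]
        for j0 in range(i0, d, block_size):
            r_blk = zi @ z[j0:j0 + block_size].T / denom
            np.clip(r_blk, -1.0, 1.0, out=r_blk)
            ii, jj = np.nonzero(np.abs(r_blk) >= r_th)
            for bi, bj in zip(ii, jj):
                gi, gj = i0 + int(bi), j0 + int(bj)
                if gi >= gj:
                    continue
                w = abs(float(r_blk[bi, bj])) if weighted else 1.0
                edges[_key(str(genes[gi]), str(genes[gj]))] = w
    return Network(
        stage=stage,
        nodes={str(g) for g in genes},
        edges=edges,
        r_th=r_th,
        weighted=weighted,
    )


def stage_unique_network(target: Network, others) -> Network:
    """Edges of ``target`` present in no other stage-specific network.

    Membership is decided on the unordered gene pair only; surviving edges
    keep the target's weights.
    """
    shared: set[Edge] = set()
    for other in others:
        shared |= set(other.edges)
    return Network(
        stage=target.stage,
        nodes=set(target.nodes),
        edges={e: w for e, w in target.edges.items() if e not in shared},
        r_th=target.r_th,
        weighted=target.weighted,
    )


def gene_weights(network: Network) -> dict[str, float]:
    """Sum of incident edge weights per gene; isolated genes get 0."""
    w = {g: 0.0 for g in network.nodes}
    for (a, b), val in network.edges.items():
        w[a] = w.get(a, 0.0) + val
        w[b] = w.get(b, 0.0) + val
    return w


def extract_key_subnetwork(
    key_genes,
    ppi: ScoredEdgeList,
    master,
    stage_net: Network,
    score_min: float = 0.4,
    max_neighbors: int = 20,
) -> Network:
    """Stage subnetwork of key genes and their strongest PPI partners.

    For each key gene, PPI partners with score >= ``score_min`` are ranked
    by descending score (ties broken lexicographically by partner id) and
    truncated to ``max_neighbors``. The union of key genes and retained
    partners, intersected with the master DEG list, induces the subgraph of
    the stage-specific network (|PCC| weights preserved).
    """
    key_genes = list(key_genes)
    if not key_genes:
        raise ValueError("key_genes must be non-empty")
    selected: set[str] = set(key_genes)
    for g in key_genes:
        partners = [
            (p, s) for p, s in ppi.partners_of(g).items() if s >= score_min
        ]
        partners.sort(key=lambda ps: (-ps[1], ps[0]))
        selected.update(p for p, _ in partners[:max_neighbors])
    node_set = selected & set(master)
    sub = stage_net.induced_subgraph(node_set)
    # genes absent from this stage's network stay as isolated nodes
    sub.nodes = set(node_set)
    return sub
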