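"""Community detection and cross-stage partition comparison.

Louvain modularity maximization (both phases, seeded sweep order,
deterministic tie-breaks), Newman modularity, contingency-table NMI with
sum-of-entropies normalization, Jaccard matching of communities, a
degree-preserving double-edge-swap null model, and the NMI permutation
test used to judge whether two stages' community structures are more
similar than expected for networks of the same size and degree sequence.

Louvain operates on the edge-bearing subgraph: genes isolated by
thresholding carry no community signal and are excluded from partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import Network, _key

__all__ = [
    "Partition",
    "modularity",
    "louvain",
    "nmi",
    "jaccard_matrix",
    "degree_preserving_randomize",
    "nmi_permutation_test",
    "PermutationTestResult",
]


@dataclass
class Partition:
    """Node -> community assignment with its modularity score."""

    assignment: dict[str, int]
    q: float

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, set()).add(node)
        return out

    def restrict(self, nodes) -> "Partition":
        keep = set(nodes)
        sub = {n: c for n, c in self.assignment.items() if n in keep}
        return Partition(_relabel(sub), self.q)

    def n_communities(self) -> int:
        return len(set(self.assignment.values()))


def _relabel(assignment: dict[str, int]) -> dict[str, int]:
    """Dense community ids from 0, ordered by sorted node appearance."""
    mapping: dict[int, int] = {}
    out: dict[str, int] = {}
    for node in sorted(assignment):
        c = assignment[node]
        if c not in mapping:
            mapping[c] = len(mapping)
        out[node] = mapping[c]
    return out


def modularity(network: Network, partition: Partition | dict[str, int]) -> float:
    """Newman modularity Q = sum_c [W_c/W - (S_c/2W)^2] over communities."""
    assignment = partition.assignment if isinstance(partition, Partition) else partition
    total = sum(network.edges.values())
    if total <= 0:
        raise ValueError("modularity undefined for an empty edge set")
    intra: dict[int, float] = {}
    strength: dict[int, float] = {}
    for (a, b), w in network.edges.items():
        ca, cb = assignment[a], assignment[b]
        strength[ca] = strength.get(ca, 0.0) + w
        strength[cb] = strength.get(cb, 0.0) + w
        if ca == cb:
            intra[ca] = intra.get(ca, 0.0) + w
    q = 0.0
    for c in strength:
        q += intra.get(c, 0.0) / total - (strength[c] / (2.0 * total)) ** 2
    return q


# ---------------------------------------------------------------------------
# Louvain


class _Aggregate:
    """Weighted graph with self-loops, for the aggregation phase."""

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.self_w: dict[int, float] = {}

    @classmethod
    def from_network(cls, network: Network, order: dict[str, int]) -> "_Aggregate":
        g = cls()
        for n in order.values():
            g.adj[n] = {}
            g.self_w[n] = 0.0
        for (a, b), w in network.edges.items():
            i, j = order[a], order[b]
            g.adj[i][j] = g.adj[i].get(j, 0.0) + w
            g.adj[j][i] = g.adj[j].get(i, 0.0) + w
        return g

    def strength(self, i: int) -> float:
        return sum(self.adj[i].values()) + 2.0 * self.self_w[i]

    def total_weight(self) -> float:
        return sum(sum(nb.values()) for nb in self.adj.values()) / 2.0 + sum(
            self.self_w.values()
        )


def _one_level(
    g: _Aggregate, rng: np.random.Generator, tol: float
) -> tuple[dict[int, int], bool]:
    """Phase one: local moves until no node improves modularity by > tol."""
    nodes = sorted(g.adj)
    comm = {n: n for n in nodes}
    k = {n: g.strength(n) for n in nodes}
    sigma_tot = {n: k[n] for n in nodes}
    two_w = sum(k.values())
    if two_w == 0.0:
        return comm, False
    improved_any = False
    while True:
        moved = False
        order = list(nodes)
        rng.shuffle(order)
        for n in order:
            old = comm[n]
            # weights from n to each neighboring community
            links: dict[int, float] = {}
            for nb, w in g.adj[n].items():
                links[comm[nb]] = links.get(comm[nb], 0.0) + w
            sigma_tot[old] -= k[n]
            comm[n] = -1
            candidates = set(links) | {old}
            best_c, best_gain = old, links.get(old, 0.0) - sigma_tot[old] * k[n] / two_w
            for c in sorted(candidates):
                gain = links.get(c, 0.0) - sigma_tot[c] * k[n] / two_w
                if gain > best_gain + tol or (
                    abs(gain - best_gain) <= tol and c < best_c
                ):
                    best_c, best_gain = c, gain
            comm[n] = best_c
            sigma_tot[best_c] += k[n]
            if best_c != old:
                moved = True
                improved_any = True
        if not moved:
            break
    return comm, improved_any


def _aggregate(g: _Aggregate, comm: dict[int, int]) -> tuple[_Aggregate, dict[int, int]]:
    labels = sorted(set(comm.values()))
    dense = {c: i for i, c in enumerate(labels)}
    out = _Aggregate()
    for i in range(len(labels)):
        out.adj[i] = {}
        out.self_w[i] = 0.0
    for n, nbs in g.adj.items():
        cn = dense[comm[n]]
        out.self_w[cn] += g.self_w[n]
        for m, w in nbs.items():
            if m < n:
                continue  # visit each undirected pair once
            cm = dense[comm[m]]
            if cn == cm:
                out.self_w[cn] += w
            else:
                out.adj[cn][cm] = out.adj[cn].get(cm, 0.0) + w
                out.adj[cm][cn] = out.adj[cm].get(cn, 0.0) + w
    return out, dense


def louvain(network: Network, seed: int = 0, tol: float = 1e-7) -> Partition:
    """Two-phase Louvain on the edge-bearing subgraph of ``network``.

    Sweep order is shuffled by ``seed``; ties in modularity gain break
    toward the lowest community id. The returned ``q`` is recomputed from
    the final assignment with :func:`modularity`.
    """
    if not network.edges:
        raise ValueError("louvain needs at least one edge")
    rng = np.random.default_rng(seed)
    nodes = sorted(network.edge_bearing_nodes())
    order = {n: i for i, n in enumerate(nodes)}
    g = _Aggregate.from_network(network, order)
    # membership of original node index in the current aggregate
    member = {i: i for i in range(len(nodes))}
    prev_q = None
    while True:
        comm, improved = _one_level(g, rng, tol)
        assignment = {n: comm[member[order[n]]] for n in nodes}
        q = modularity(network, _relabel(assignment))
        if prev_q is not None and q - prev_q < tol:
            break
        prev_q = q
        if not improved:
            break
        g, dense = _aggregate(g, comm)
        member = {i: dense[comm[member[i]]] for i in member}
    final = _relabel({n: comm[member[order[n]]] for n in nodes})
    return Partition(final, modularity(network, final))


# ---------------------------------------------------------------------------
# partition comparison


def nmi(a: Partition, b: Partition) -> float:
    """Normalized mutual information with sum-of-entropies normalization.

    NMI = -2 sum_ij N_ij ln(N_ij N / (N_i N_j)) /
          (sum_i N_i ln(N_i/N) + sum_j N_j ln(N_j/N)).
    1 for identical partitions; 0 when either partition is a single
    community and the two are not identical.
    """
    if set(a.assignment) != set(b.assignment):
        raise ValueError("nmi requires partitions over the same node set")
    nodes = sorted(a.assignment)
    n = len(nodes)
    if n == 0:
        raise ValueError("nmi undefined on empty node set")
    la = [a.assignment[x] for x in nodes]
    lb = [b.assignment[x] for x in nodes]
    table: dict[tuple[int, int], int] = {}
    row: dict[int, int] = {}
    col: dict[int, int] = {}
    for ca, cb in zip(la, lb):
        table[(ca, cb)] = table.get((ca, cb), 0) + 1
        row[ca] = row.get(ca, 0) + 1
        col[cb] = col.get(cb, 0) + 1
    identical = _relabel(a.assignment) == _relabel(b.assignment)
    if identical:
        return 1.0
    h_a = sum(c * np.log(c / n) for c in row.values())
    h_b = sum(c * np.log(c / n) for c in col.values())
    if h_a == 0.0 or h_b == 0.0:
        return 0.0  # a single-community partition carries no information
    num = sum(
        cnt * np.log(cnt * n / (row[i] * col[j]))
        for (i, j), cnt in table.items()
    )
    val = -2.0 * num / (h_a + h_b)
    return float(min(1.0, max(0.0, val)))


def jaccard_matrix(a: Partition, b: Partition) -> np.ndarray:
    """J[i, j] = |C_i ∩ D_j| / |C_i ∪ D_j| over communities sorted by id."""
    ca = [a.communities()[c] for c in sorted(a.communities())]
    cb = [b.communities()[c] for c in sorted(b.communities())]
    out = np.zeros((len(ca), len(cb)))
    for i, s in enumerate(ca):
        for j, t in enumerate(cb):
            union = len(s | t)
            out[i, j] = len(s & t) / union if union else 0.0
    return out


# ---------------------------------------------------------------------------
# degree-preserving null model


def degree_preserving_randomize(
    network: Network, n_swaps: int | None = None, seed: int = 0
) -> Network:
    """Rewire by attempted double-edge swaps; degree multiset is invariant.

    Each attempt picks two distinct edges and one of the two endpoint
    exchanges; attempts creating a self-loop or a duplicate edge are
    rejected. Edge weights travel with the rewired edges, preserving the
    weight multiset. Default ``n_swaps`` is 10x the edge count.
    """
    if network.n_edges < 2:
        raise ValueError("randomization needs at least 2 edges")
    if n_swaps is None:
        n_swaps = 10 * network.n_edges
    rng = np.random.default_rng(seed)
    edges = [(a, b, w) for (a, b), w in sorted(network.edges.items())]
    present = {(a, b) for a, b, _ in edges}
    m = len(edges)
    draws = rng.integers(m, size=(n_swaps, 2))
    flips = rng.integers(2, size=n_swaps)
    for t in range(n_swaps):
        i, j = int(draws[t, 0]), int(draws[t, 1])
        if i == j:
            continue
        a, b, w1 = edges[i]
        x, y, w2 = edges[j]
        if flips[t]:
            x, y = y, x
        # propose (a, x) and (b, y)
        if a == x or b == y:
            continue
        e1, e2 = _key(a, x), _key(b, y)
        if e1 == e2 or e1 in present or e2 in present:
            continue
        present.discard(_key(a, b))
        present.discard(_key(x, y))
        present.add(e1)
        present.add(e2)
        edges[i] = (*e1, w1)
        edges[j] = (*e2, w2)
    return Network(
        stage=network.stage,
        nodes=set(network.nodes),
        edges={_key(a, b): w for a, b, w in edges},
        r_th=network.r_th,
        weighted=network.weighted,
    )


@dataclass
class PermutationTestResult:
    observed_nmi: float
    null_nmis: np.ndarray
    p_value: float
    seed: int


def _nmi_common(pa: Partition, pb: Partition) -> float:
    common = set(pa.assignment) & set(pb.assignment)
    if not common:
        raise ValueError("partitions share no nodes")
    return nmi(pa.restrict(common), pb.restrict(common))


def nmi_permutation_test(
    net_a: Network,
    net_b: Network,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """Upper-tail permutation test of community similarity between stages.

    Observed statistic: NMI between the Louvain partitions of the two
    networks (on their common edge-bearing nodes). Null: both networks are
    independently degree-preservingly rewired, communities re-detected and
    NMI recorded, ``n_perm`` times. p = (1 + #{null >= observed}) /
    (1 + n_perm), so the smallest attainable p is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n_perm + 2) % (2**31)
    pa = louvain(net_a, seed=int(seeds[0]))
    pb = louvain(net_b, seed=int(seeds[1]))
    observed = _nmi_common(pa, pb)
    null = np.empty(n_perm)
    for r in range(n_perm):
        sa, sb = int(seeds[2 + 2 * r]), int(seeds[3 + 2 * r])
        ra = degree_preserving_randomize(net_a, seed=sa)
        rb = degree_preserving_randomize(net_b, seed=sb)
        null[r] = _nmi_common(louvain(ra, seed=sa), louvain(rb, seed=sb))
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_perm)
    return PermutationTestResult(observed, null, p, seed)
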