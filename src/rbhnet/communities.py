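"""Subnetwork isolation, Markov clustering and network summary statistics.

The subnetwork of interest keeps one sign of RBH edge between two disease
groups (e.g. negative edges between groups "AD" and "LC"). Markov
clustering (MCL) is run on the ``|rho|``-weighted adjacency with self-loops;
communities are read off the attractor structure of the converged flow
matrix. Summary statistics mirror the usual network comparisons: modularity
of the partition, average local clustering coefficient, community counts and
sizes, and the number of edges whose two endpoint components are both
significantly case/control differential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import spearmanr

from rbhnet.decomposition import ComponentRef, Decomposition
from rbhnet.io_expression import FoldChangeVector
from rbhnet.rbh_network import RBHEdge, RBHNetwork


@dataclass
class Subnetwork:
    """Sign- and group-filtered slice of an RBH network."""

    nodes: set[ComponentRef]
    edges: set[RBHEdge]
    selection: dict = field(default_factory=dict)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n, dataset=n.dataset_id, disease_group=n.disease_group)
        for e in self.edges:
            g.add_edge(e.endpoint_a, e.endpoint_b, sign=e.sign, weight=e.weight,
                       similarity=abs(e.weight))
        return g


@dataclass
class CommunityPartition:
    """MCL communities of a subnetwork (disjoint node sets, integer ids)."""

    communities: list[set[ComponentRef]]
    inflation: float
    n_iterations: int = 0

    def __post_init__(self) -> None:
        seen: set[ComponentRef] = set()
        for c in self.communities:
            if seen & c:
                raise ValueError("communities must be disjoint")
            seen |= c

    def membership(self) -> dict[ComponentRef, int]:
        return {n: i for i, c in enumerate(self.communities) for n in c}

    def sizes(self) -> list[int]:
        return [len(c) for c in self.communities]


def extract_subnetwork(
    net: RBHNetwork, group_a: str, group_b: str, sign: str
) -> Subnetwork:
    """Keep edges with the requested sign joining ``group_a`` to ``group_b``.

    Only nodes incident to a kept edge are retained.
    """
    if sign not in ("+", "-"):
        raise ValueError(f"invalid sign {sign!r}")
    groups = {n.disease_group for n in net.nodes}
    for g in (group_a, group_b):
        if g not in groups:
            raise ValueError(f"unknown disease group {g!r}; network has {sorted(groups)}")
    wanted = {group_a, group_b}
    edges = {
        e for e in net.edges
        if e.sign == sign
        and {e.endpoint_a.disease_group, e.endpoint_b.disease_group} == wanted
    }
    nodes = {e.endpoint_a for e in edges} | {e.endpoint_b for e in edges}
    return Subnetwork(
        nodes=nodes, edges=edges,
        selection={"sign": sign, "groups": sorted(wanted)},
    )


def _mcl_matrix(
    M: np.ndarray, inflation: float, expansion: int, max_iter: int, tol: float
) -> tuple[np.ndarray, int]:
    """Iterate expansion/inflation on a column-stochastic matrix."""
    for it in range(1, max_iter + 1):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        M[M < 1e-12] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.abs(M - prev).max() < tol:
            return M, it
    residual = float(np.abs(M - prev).max())
    raise RuntimeError(
        f"MCL did not converge within {max_iter} iterations (residual {residual:.3e})"
    )


def _read_clusters(M: np.ndarray) -> list[set[int]]:
    """Communities from the converged flow matrix's attractor rows."""
    n = M.shape[0]
    attractors = [i for i in range(n) if M[i, i] > 1e-8]
    clusters: list[set[int]] = []
    for a in attractors:
        members = set(np.where(M[a, :] > 1e-8)[0])
        members.add(a)
        merged = False
        for c in clusters:
            if c & members:
                c |= members
                merged = True
                break
        if not merged:
            clusters.append(members)
    # merge any remaining overlaps, then sweep up orphans
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters.pop(j)
                    changed = True
                    break
            if changed:
                break
    assigned = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in assigned:
            owner = int(np.argmax(M[:, i]))
            placed = False
            for c in clusters:
                if owner in c:
                    c.add(i)
                    placed = True
                    break
            if not placed:
                clusters.append({i})
    return clusters


def mcl(
    sub: Subnetwork,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> CommunityPartition:
    """Weighted Markov clustering of a subnetwork.

    Similarities are ``|rho|``; each node gets a self-loop weighted by its
    maximum incident similarity. The column-normalized matrix is iterated
    with expansion (matrix power) and inflation (entrywise power plus
    renormalization) until the flow matrix stabilizes; communities are the
    attractor basins. Singletons are retained as size-1 communities.
    """
    if not sub.nodes:
        raise ValueError("cannot cluster an empty subnetwork")
    nodes = sorted(sub.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    for e in sub.edges:
        i, j = idx[e.endpoint_a], idx[e.endpoint_b]
        W[i, j] = W[j, i] = abs(e.weight)
    loops = W.max(axis=1)
    loops[loops == 0] = 1.0
    W[np.diag_indices(n)] = loops
    M = W / W.sum(axis=0, keepdims=True)
    M, iters = _mcl_matrix(M, inflation, expansion, max_iter, tol)
    clusters = _read_clusters(M)
    communities = [
        {nodes[i] for i in c}
        for c in sorted(clusters, key=lambda c: (-len(c), min(c)))
    ]
    return CommunityPartition(communities=communities, inflation=inflation,
                              n_iterations=iters)


def network_stats(
    sub: Subnetwork,
    part: CommunityPartition,
    min_size: int = 4,
    weighted: bool = False,
) -> dict:
    """Topology and partition summary for a subnetwork.

    Returns node/edge counts, Newman-Girvan modularity of the partition,
    average local clustering coefficient, and the count plus mean size of
    communities with at least ``min_size`` members. Both modularity and
    clustering are unweighted by default; ``weighted=True`` uses ``|rho|``.
    """
    if not sub.nodes:
        raise ValueError("empty subnetwork")
    g = sub.to_graph()
    member = part.membership()
    groups: dict[int, set[ComponentRef]] = {}
    for node in g.nodes:
        groups.setdefault(member.get(node, -1 - len(groups)), set()).add(node)
    communities = list(groups.values())
    weight_key = "similarity" if weighted else None
    modularity = nx.algorithms.community.modularity(g, communities, weight=weight_key)
    avg_clust = nx.average_clustering(g, weight=weight_key)
    big = [c for c in part.communities if len(c) >= min_size]
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "modularity": modularity,
        "avg_clustering": avg_clust,
        "n_communities": len(part.communities),
        "n_communities_min_size": len(big),
        "mean_size_min_size": float(np.mean([len(c) for c in big])) if big else 0.0,
    }


def significant_edges(
    sub: Subnetwork,
    decomps: list[Decomposition],
    alpha: float = 0.05,
    both_endpoints: bool = True,
) -> int:
    """Count subnetwork edges whose endpoint components are significant.

    Significance is the per-component two-sided case-vs-control Wilcoxon
    p-value recorded during disease-pointing orientation. By default both
    endpoints must satisfy ``p < alpha``; ``both_endpoints=False`` requires
    only one.
    """
    pmap: dict[tuple[str, int], float] = {}
    for d in decomps:
        if d.p_values is None:
            raise ValueError(
                f"{d.dataset_id}: no case/control p-values "
                "(orient with disease_pointing first)"
            )
        for i, p in enumerate(d.p_values):
            pmap[(d.dataset_id, i + 1)] = float(p)

    def _p(ref: ComponentRef) -> float:
        key = (ref.dataset_id, ref.component_index)
        if key not in pmap:
            raise ValueError(f"no p-value for component {ref}")
        return pmap[key]

    count = 0
    for e in sub.edges:
        sig_a = _p(e.endpoint_a) < alpha
        sig_b = _p(e.endpoint_b) < alpha
        if (sig_a and sig_b) if both_endpoints else (sig_a or sig_b):
            count += 1
    return count


def metagene_fc_correlation(
    decomps: list[Decomposition],
    fold_changes: dict[str, FoldChangeVector],
) -> dict[tuple[str, int], float]:
    """Spearman rho of every metagene vs. its dataset's fold-change vector."""
    out: dict[tuple[str, int], float] = {}
    for d in decomps:
        fc = fold_changes.get(d.dataset_id)
        if fc is None:
            raise ValueError(f"no fold-change vector for dataset {d.dataset_id!r}")
        if list(fc.gene_ids) != list(d.gene_ids):
            raise ValueError(
                f"{d.dataset_id}: gene ids of fold-change vector do not match metagenes"
            )
        for i in range(d.k):
            rho = spearmanr(d.metagenes[:, i], fc.values).statistic
            out[(d.dataset_id, i + 1)] = float(rho)
    return out
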