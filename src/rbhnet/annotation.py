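"""Community annotation: consensus metagenes, top genes, enrichment, subtypes.

A community's consensus metagene is the gene-wise average of its member
metagenes after aligning signs along the community's own RBH edges toward a
reference member (breadth-first sign propagation, multiplying by the sign of
each traversed edge's correlation). Top-contributing genes are those beyond
``z`` standard deviations of the consensus weights, split into up/down by
sign. Over-representation is a one-sided Fisher exact (hypergeometric upper
tail) with Bonferroni correction across a signature collection.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu

from rbhnet.decomposition import ComponentRef, Decomposition
from rbhnet.communities import CommunityPartition, Subnetwork
from rbhnet.rbh_network import signed_rbh_pair

logger = logging.getLogger(__name__)


@dataclass
class SignatureCollection:
    """Named gene sets (GMT-style), symbols upper-cased."""

    name: str
    signatures: dict[str, set[str]]

    def __post_init__(self) -> None:
        for sig, genes in self.signatures.items():
            if not genes:
                raise ValueError(f"signature {sig!r} is empty")
        self.signatures = {
            sig: {g.upper() for g in genes} for sig, genes in self.signatures.items()
        }

    def __len__(self) -> int:
        return len(self.signatures)


@dataclass
class ConsensusMetagene:
    """Average of a community's sign-aligned member metagenes."""

    community_id: int
    gene_ids: list[str]
    weights: np.ndarray
    n_members: int
    reference_group: str
    sign_consistent: bool = True

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.gene_ids) != self.weights.shape[0]:
            raise ValueError("consensus weights do not match gene ids")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("consensus weights must be finite")


@dataclass
class EnrichmentResult:
    """One signature's overlap test against one gene set."""

    community_id: int
    direction: str  # "up" or "down"
    signature: str
    overlap: int
    p_raw: float
    p_adjusted: float


def read_gmt(path: str) -> SignatureCollection:
    """Parse a GMT file: per line, name TAB description TAB gene symbols."""
    signatures: dict[str, set[str]] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            name = fields[0].strip()
            genes = {g.strip() for g in fields[2:] if g.strip()}
            if not genes:
                raise ValueError(f"{path}:{lineno}: signature {name!r} has no genes")
            signatures[name] = genes
    if n_lines == 0:
        raise ValueError(f"{path}: empty GMT file")
    return SignatureCollection(name=str(path), signatures=signatures)


def _member_edges(community: set[ComponentRef], sub: Subnetwork):
    return [
        e for e in sub.edges
        if e.endpoint_a in community and e.endpoint_b in community
    ]


def consensus_metagene(
    community: set[ComponentRef],
    decomps: list[Decomposition],
    sub: Subnetwork,
    reference_group: str,
    community_id: int = 0,
) -> ConsensusMetagene:
    """Sign-align a community's metagenes along its edges and average them.

    The reference member is the lowest (dataset_id, component_index) node of
    ``reference_group`` (falling back to the lowest overall when the group is
    absent). Signs propagate by BFS: crossing an edge multiplies the running
    sign by the sign of that edge's correlation. Sign-inconsistent cycles are
    resolved by the BFS tree and flagged. The consensus is the gene-wise
    average over those members in which the gene occurs.
    """
    if not community:
        raise ValueError("community is empty")
    dmap = {d.dataset_id: d for d in decomps}
    for ref in community:
        if ref.dataset_id not in dmap:
            raise ValueError(f"no decomposition for {ref}")

    in_group = sorted(r for r in community if r.disease_group == reference_group)
    if in_group:
        root = in_group[0]
    else:
        logger.warning(
            "community %d has no member in reference group %r; using lowest member",
            community_id, reference_group,
        )
        root = sorted(community)[0]

    edges = _member_edges(community, sub)
    adj: dict[ComponentRef, list[tuple[ComponentRef, float]]] = {r: [] for r in community}
    for e in edges:
        s = 1.0 if e.weight > 0 else -1.0
        adj[e.endpoint_a].append((e.endpoint_b, s))
        adj[e.endpoint_b].append((e.endpoint_a, s))

    signs: dict[ComponentRef, float] = {root: 1.0}
    consistent = True
    queue = deque([root])
    while queue:
        cur = queue.popleft()
        for nxt, s in adj[cur]:
            want = signs[cur] * s
            if nxt in signs:
                if signs[nxt] != want:
                    consistent = False
                    logger.warning(
                        "sign-inconsistent cycle at %s in community %d; keeping BFS tree sign",
                        nxt, community_id,
                    )
                continue
            signs[nxt] = want
            queue.append(nxt)
    if len(signs) != len(community):
        missing = sorted(set(community) - set(signs))
        raise ValueError(
            f"community {community_id} is disconnected; unreachable members: "
            f"{[str(m) for m in missing]}"
        )

    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    gene_order: list[str] = []
    for ref in sorted(community):
        d = dmap[ref.dataset_id]
        vec = signs[ref] * d.metagenes[:, ref.component_index - 1]
        for g, w in zip(d.gene_ids, vec):
            if g not in sums:
                sums[g] = 0.0
                counts[g] = 0
                gene_order.append(g)
            sums[g] += float(w)
            counts[g] += 1
    weights = np.array([sums[g] / counts[g] for g in gene_order])
    return ConsensusMetagene(
        community_id=community_id,
        gene_ids=gene_order,
        weights=weights,
        n_members=len(community),
        reference_group=reference_group,
        sign_consistent=consistent,
    )


def top_genes(cm: ConsensusMetagene, z: float = 3.0) -> tuple[set[str], set[str]]:
    """Genes beyond ``z`` standard deviations of the consensus weights.

    Returns ``(up, down)``: up = weights above ``+z*SD``, down = below
    ``-z*SD``, with the SD taken over all consensus weights.
    """
    if len(cm.gene_ids) < 10:
        raise ValueError("need at least 10 genes in the consensus metagene")
    sd = float(np.std(cm.weights, ddof=1))
    if sd == 0:
        raise ValueError("consensus weights have zero standard deviation")
    up = {g for g, w in zip(cm.gene_ids, cm.weights) if w > z * sd}
    down = {g for g, w in zip(cm.gene_ids, cm.weights) if w < -z * sd}
    return up, down


def enrich(
    gene_set: set[str],
    coll: SignatureCollection,
    universe: set[str],
    community_id: int = 0,
    direction: str = "up",
) -> list[EnrichmentResult]:
    """One-sided Fisher exact (hypergeometric upper tail) per signature.

    The 2x2 table is restricted to ``universe``; the Bonferroni factor is
    the number of signatures in the collection.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_set:
        raise ValueError("empty gene set")
    gene_set = {g.upper() for g in gene_set}
    universe = {g.upper() for g in universe}
    if not gene_set <= universe:
        raise ValueError("gene set must be a subset of the universe")
    N = len(universe)
    n_draw = len(gene_set)
    n_tests = len(coll)
    results = []
    for sig_name, sig_genes in coll.signatures.items():
        K = len(sig_genes & universe)
        overlap = len(gene_set & sig_genes)
        p_raw = float(hypergeom.sf(overlap - 1, N, K, n_draw)) if K else 1.0
        results.append(
            EnrichmentResult(
                community_id=community_id,
                direction=direction,
                signature=sig_name,
                overlap=overlap,
                p_raw=p_raw,
                p_adjusted=min(1.0, p_raw * n_tests),
            )
        )
    return sorted(results, key=lambda r: r.p_raw)


def subtype_association(
    weights: np.ndarray,
    subtypes: list[str],
    n_extra_tests: int = 1,
) -> dict[str, tuple[float, float]]:
    """Two-sided rank-sum test of each subtype's weights vs. all others.

    Returns ``{subtype: (p_raw, p_adjusted)}``; Bonferroni multiplies by the
    number of subtypes times ``n_extra_tests`` (e.g. the number of components
    when applied network-wide).
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(subtypes):
        raise ValueError("weights and subtype labels differ in length")
    levels = sorted(set(subtypes))
    if len(levels) < 2:
        raise ValueError("need at least two subtypes")
    counts = {lv: subtypes.count(lv) for lv in levels}
    small = [lv for lv, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"subtypes with fewer than 2 samples: {small}")
    n_tests = len(levels) * max(1, n_extra_tests)
    out: dict[str, tuple[float, float]] = {}
    for lv in levels:
        mask = np.array([s == lv for s in subtypes])
        a, b = weights[mask], weights[~mask]
        if np.all(weights == weights[0]):
            p = 1.0
        else:
            p = float(mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)
        out[lv] = (p, min(1.0, p * n_tests))
    return out


def _table_as_decomposition(
    table: pd.DataFrame, dataset_id: str, disease_group: str
) -> Decomposition:
    """Wrap an external gene-by-component weight table for RBH computation."""
    A = table.to_numpy(dtype=float)
    n, k = A.shape
    return Decomposition(
        dataset_id=dataset_id,
        disease_group=disease_group,
        metagenes=A,
        metasamples=np.zeros((k, max(k, 1))),
        gene_ids=list(table.index.astype(str)),
        sample_ids=[f"_ext{i}" for i in range(max(k, 1))],
        stability=np.ones(k),
        seed=0,
    )


def match_external_metagenes(
    externals: dict[str, pd.DataFrame],
    decomps: list[Decomposition],
    sub: Subnetwork,
    part: CommunityPartition,
    min_shared_genes: int = 500,
    rho_cutoff: float = 0.3,
) -> dict[int, int]:
    """Count, per community, external tables with >=1 RBH onto a member.

    ``externals`` maps a name (e.g. a cancer type) to a gene-by-component
    weight table. Both RBH signs qualify (external orientation is undefined)
    subject to ``|rho| >= rho_cutoff``. Tables sharing fewer than
    ``min_shared_genes`` genes with a dataset are skipped for that dataset
    (with a warning); a table overlapping no dataset contributes nothing.
    """
    members = {n for c in part.communities for n in c}
    node_comm = {n: i for i, c in enumerate(part.communities) for n in c}
    sub_datasets = {n.dataset_id for n in sub.nodes}
    use = [d for d in decomps if d.dataset_id in sub_datasets]

    hits: dict[int, set[str]] = {i: set() for i in range(len(part.communities))}
    for name, table in externals.items():
        ext = _table_as_decomposition(table, f"__ext_{name}", "__external")
        for d in use:
            try:
                edges = signed_rbh_pair(ext, d, min_shared_genes=min_shared_genes)
            except ValueError as err:
                logger.warning("skipping external %r vs %s: %s", name, d.dataset_id, err)
                continue
            for e in edges:
                if abs(e.weight) < rho_cutoff:
                    continue
                inner = e.endpoint_b if e.endpoint_a.dataset_id == ext.dataset_id else e.endpoint_a
                inner = ComponentRef(inner.dataset_id, inner.component_index,
                                     d.disease_group)
                if inner in members:
                    hits[node_comm[inner]].add(name)
    return {cid: len(names) for cid, names in hits.items()}
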