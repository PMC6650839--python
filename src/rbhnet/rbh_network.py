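"""Signed reciprocal-best-hit (RBH) networks between decompositions.

Two metagenes from different datasets form a positive RBH when their
Spearman correlation over shared genes is positive and is simultaneously the
row maximum and the column maximum of the cross-correlation table; a
negative RBH analogously requires a negative, mutually minimal correlation.
Each component can therefore hit at most one positive and one negative
partner per other dataset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from rbhnet.decomposition import ComponentRef, Decomposition

logger = logging.getLogger(__name__)

DEFAULT_MIN_SHARED_GENES = 500


@dataclass(frozen=True)
class RBHEdge:
    """One signed reciprocal best hit between components of two datasets."""

    endpoint_a: ComponentRef
    endpoint_b: ComponentRef
    sign: str  # "+" or "-"
    weight: float  # Spearman rho over shared genes
    n_shared_genes: int

    def __post_init__(self) -> None:
        if self.endpoint_a.dataset_id == self.endpoint_b.dataset_id:
            raise ValueError("RBH endpoints must belong to different datasets")
        if self.sign not in ("+", "-"):
            raise ValueError(f"invalid sign {self.sign!r}")
        if self.sign == "+" and not self.weight > 0:
            raise ValueError("+RBH requires positive weight")
        if self.sign == "-" and not self.weight < 0:
            raise ValueError("-RBH requires negative weight")

    def canonical(self) -> "RBHEdge":
        """Endpoints sorted by (dataset_id, index) for set semantics."""
        a, b = self.endpoint_a, self.endpoint_b
        if (a.dataset_id, a.component_index) <= (b.dataset_id, b.component_index):
            return self
        return RBHEdge(b, a, self.sign, self.weight, self.n_shared_genes)


@dataclass
class RBHNetwork:
    """Signed, weighted graph over (dataset, component) nodes."""

    nodes: set[ComponentRef] = field(default_factory=set)
    edges: set[RBHEdge] = field(default_factory=set)

    def add_edges(self, edges: set[RBHEdge]) -> None:
        self.edges |= {e.canonical() for e in edges}

    def edges_of(self, ref: ComponentRef) -> list[RBHEdge]:
        return [
            e for e in self.edges
            if ref in (e.endpoint_a, e.endpoint_b)
        ]

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n, dataset=n.dataset_id, disease_group=n.disease_group)
        for e in self.edges:
            g.add_edge(
                e.endpoint_a, e.endpoint_b,
                sign=e.sign, weight=e.weight, n_shared_genes=e.n_shared_genes,
            )
        return g

    # -- persistence -----------------------------------------------------
    def to_edgelist(self) -> pd.DataFrame:
        rows = [
            {
                "dataset_a": e.endpoint_a.dataset_id,
                "component_a": e.endpoint_a.component_index,
                "group_a": e.endpoint_a.disease_group,
                "dataset_b": e.endpoint_b.dataset_id,
                "component_b": e.endpoint_b.component_index,
                "group_b": e.endpoint_b.disease_group,
                "sign": e.sign,
                "rho": e.weight,
                "n_shared_genes": e.n_shared_genes,
            }
            for e in sorted(
                self.edges,
                key=lambda e: (
                    e.endpoint_a.dataset_id, e.endpoint_a.component_index,
                    e.endpoint_b.dataset_id, e.endpoint_b.component_index, e.sign,
                ),
            )
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "dataset_a", "component_a", "group_a",
                "dataset_b", "component_b", "group_b",
                "sign", "rho", "n_shared_genes",
            ],
        )

    def save(self, path: str | Path) -> None:
        # repr gives shortest round-trip floats (default %.16g may lose a bit)
        self.to_edgelist().to_csv(
            path, sep="\t", index=False, float_format=lambda x: repr(float(x))
        )

    @classmethod
    def from_edgelist(cls, df: pd.DataFrame,
                      nodes: set[ComponentRef] | None = None) -> "RBHNetwork":
        net = cls(nodes=set(nodes) if nodes else set())
        for row in df.itertuples(index=False):
            a = ComponentRef(str(row.dataset_a), int(row.component_a), str(row.group_a))
            b = ComponentRef(str(row.dataset_b), int(row.component_b), str(row.group_b))
            net.edges.add(RBHEdge(a, b, str(row.sign), float(row.rho),
                                  int(row.n_shared_genes)).canonical())
            net.nodes |= {a, b}
        return net

    @classmethod
    def load(cls, path: str | Path) -> "RBHNetwork":
        return cls.from_edgelist(
            pd.read_csv(path, sep="\t", float_precision="round_trip")
        )


def _spearman_cross(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All-pairs Spearman rho between columns of A and columns of B."""
    Ra = np.apply_along_axis(rankdata, 0, A)
    Rb = np.apply_along_axis(rankdata, 0, B)
    Ra = Ra - Ra.mean(axis=0, keepdims=True)
    Rb = Rb - Rb.mean(axis=0, keepdims=True)
    sa = np.sqrt((Ra**2).sum(axis=0))
    sb = np.sqrt((Rb**2).sum(axis=0))
    sa[sa == 0] = np.nan
    sb[sb == 0] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = (Ra.T @ Rb) / np.outer(sa, sb)
    return rho


def cross_correlation(
    da: Decomposition,
    db: Decomposition,
    min_shared_genes: int = DEFAULT_MIN_SHARED_GENES,
) -> pd.DataFrame:
    """k_a x k_b table of Spearman rho over the shared-gene intersection."""
    idx_a = {g: i for i, g in enumerate(da.gene_ids)}
    shared = [g for g in db.gene_ids if g in idx_a]
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"datasets {da.dataset_id!r} and {db.dataset_id!r} share only "
            f"{len(shared)} genes (< {min_shared_genes})"
        )
    idx_b = {g: i for i, g in enumerate(db.gene_ids)}
    rows_a = [idx_a[g] for g in shared]
    rows_b = [idx_b[g] for g in shared]
    rho = _spearman_cross(da.metagenes[rows_a], db.metagenes[rows_b])
    return pd.DataFrame(
        rho,
        index=[f"IC{i + 1}" for i in range(da.k)],
        columns=[f"IC{j + 1}" for j in range(db.k)],
    )


def _mutual_extrema_edges(
    rho: np.ndarray,
    da: Decomposition,
    db: Decomposition,
    n_shared: int,
) -> set[RBHEdge]:
    edges: set[RBHEdge] = set()
    refs_a = da.component_refs()
    refs_b = db.component_refs()

    row_max = rho.max(axis=1)
    col_max = rho.max(axis=0)
    row_min = rho.min(axis=1)
    col_min = rho.min(axis=0)

    for extreme, row_ext, col_ext, sign in (
        (np.argmax, row_max, col_max, "+"),
        (np.argmin, row_min, col_min, "-"),
    ):
        for i in range(rho.shape[0]):
            j = int(extreme(rho[i]))  # ties -> lowest index
            v = rho[i, j]
            if sign == "+" and not v > 0:
                continue
            if sign == "-" and not v < 0:
                continue
            # mutual: i must be (the lowest-index) extremum of column j
            j_back = int(extreme(rho[:, j]))
            if j_back != i:
                continue
            if np.count_nonzero(rho[i] == v) > 1 or np.count_nonzero(rho[:, j] == v) > 1:
                logger.warning(
                    "tied %sRBH extremum between %s and %s resolved by lowest index",
                    sign, refs_a[i], refs_b[j],
                )
            edges.add(RBHEdge(refs_a[i], refs_b[j], sign, float(v), n_shared))
    return edges


def signed_rbh_pair(
    da: Decomposition,
    db: Decomposition,
    min_shared_genes: int = DEFAULT_MIN_SHARED_GENES,
) -> set[RBHEdge]:
    """Signed reciprocal best hits between two decompositions.

    (i, j) is a +RBH iff rho(i, j) > 0 and rho(i, j) is both the maximum of
    row i and of column j; a -RBH iff rho(i, j) < 0 and mutually minimal.
    """
    if da.dataset_id == db.dataset_id:
        raise ValueError("RBHs are defined between two distinct datasets")
    table = cross_correlation(da, db, min_shared_genes=min_shared_genes)
    idx_a = {g: i for i, g in enumerate(da.gene_ids)}
    n_shared = sum(1 for g in db.gene_ids if g in idx_a)
    return _mutual_extrema_edges(table.to_numpy(), da, db, n_shared)


def build_network(
    decomps: list[Decomposition],
    min_shared_genes: int = DEFAULT_MIN_SHARED_GENES,
    weight_cutoff: float | None = None,
) -> RBHNetwork:
    """Union of signed RBHs over all unordered dataset pairs.

    All components of all decompositions become nodes, including isolated
    ones. An optional ``weight_cutoff`` drops edges with ``|rho|`` below it.
    """
    if len(decomps) < 2:
        raise ValueError("need at least two decompositions")
    ids = [d.dataset_id for d in decomps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate dataset ids among decompositions")
    orientations = {d.orientation for d in decomps}
    if len(orientations) > 1:
        raise ValueError(f"mixed orientation methods: {sorted(orientations)}")

    net = RBHNetwork()
    for d in decomps:
        net.nodes |= set(d.component_refs())
    for da, db in combinations(decomps, 2):
        edges = signed_rbh_pair(da, db, min_shared_genes=min_shared_genes)
        if weight_cutoff is not None:
            edges = {e for e in edges if abs(e.weight) >= weight_cutoff}
        net.add_edges(edges)
    return net
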