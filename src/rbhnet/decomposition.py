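"""Stabilized ICA decomposition of expression matrices and component orientation.

Each dataset is decomposed independently: FastICA is run ``n_runs`` times
from different random initializations on the row-centered matrix, the pooled
components are clustered by average-linkage agglomerative clustering on
``1 - |correlation|``, and each cluster's centrotype (the member with
maximal total within-cluster similarity) is reported as a component together
with a stability index.

Components are then oriented by one of two procedures:

* long-tail pointing — flip a component when the sample skewness of its
  metagene weights is negative, so heavy tails point to positive weights;
* disease pointing — flip a component when the rank-sum statistic of its
  case metasample weights (centered at the null expectation) is negative,
  so case activity points positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, rankdata, skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from rbhnet.io_expression import ExpressionDataset

ORIENTATIONS = ("none", "long_tail", "disease_pointing")


@dataclass(frozen=True, order=True)
class ComponentRef:
    """Identity of one component of one dataset (node of the RBH network).

    ``component_index`` is 1-based, in ``[1..k]`` of the referenced
    decomposition.
    """

    dataset_id: str
    component_index: int
    disease_group: str = field(compare=False, default="")

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.dataset_id}:IC{self.component_index}"


@dataclass
class Decomposition:
    """Result of a stabilized ICA run on one dataset.

    ``metagenes`` is the gene-by-component mixing matrix (n x k, columns =
    metagenes); ``metasamples`` is the component-by-sample source matrix
    (k x m, rows = metasamples). Component i pairs metagene column i with
    metasample row i.
    """

    dataset_id: str
    disease_group: str
    metagenes: np.ndarray
    metasamples: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    stability: np.ndarray
    seed: int
    orientation: str = "none"
    labels: list[str] | None = None
    p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.metagenes = np.asarray(self.metagenes, dtype=float)
        self.metasamples = np.asarray(self.metasamples, dtype=float)
        self.stability = np.asarray(self.stability, dtype=float)
        n, k = self.metagenes.shape
        k2, m = self.metasamples.shape
        if k != k2:
            raise ValueError("metagene columns and metasample rows are misaligned")
        if k > min(n, m):
            raise ValueError(f"k={k} exceeds min(n, m)={min(n, m)}")
        if len(self.gene_ids) != n or len(self.sample_ids) != m:
            raise ValueError("gene/sample id lengths do not match matrices")
        if self.stability.shape != (k,):
            raise ValueError("stability must have one entry per component")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def k(self) -> int:
        return self.metagenes.shape[1]

    def component_refs(self) -> list[ComponentRef]:
        return [
            ComponentRef(self.dataset_id, i + 1, self.disease_group)
            for i in range(self.k)
        ]

    # -- persistence -----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Persist as two TSV tables plus a JSON sidecar."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        comps = [f"IC{i + 1}" for i in range(self.k)]
        pd.DataFrame(self.metagenes, index=self.gene_ids, columns=comps).to_csv(
            d / f"{self.dataset_id}.metagenes.tsv", sep="\t"
        )
        pd.DataFrame(self.metasamples, index=comps, columns=self.sample_ids).to_csv(
            d / f"{self.dataset_id}.metasamples.tsv", sep="\t"
        )
        meta = {
            "dataset_id": self.dataset_id,
            "disease_group": self.disease_group,
            "k": self.k,
            "seed": self.seed,
            "orientation": self.orientation,
            "stability": self.stability.tolist(),
            "labels": self.labels,
            "p_values": None if self.p_values is None else self.p_values.tolist(),
        }
        (d / f"{self.dataset_id}.decomposition.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path, dataset_id: str) -> "Decomposition":
        d = Path(directory)
        meta = json.loads((d / f"{dataset_id}.decomposition.json").read_text())
        A = pd.read_csv(d / f"{dataset_id}.metagenes.tsv", sep="\t", index_col=0)
        S = pd.read_csv(d / f"{dataset_id}.metasamples.tsv", sep="\t", index_col=0)
        return cls(
            dataset_id=meta["dataset_id"],
            disease_group=meta["disease_group"],
            metagenes=A.to_numpy(),
            metasamples=S.to_numpy(),
            gene_ids=list(A.index.astype(str)),
            sample_ids=list(S.columns.astype(str)),
            stability=np.asarray(meta["stability"], dtype=float),
            seed=meta["seed"],
            orientation=meta["orientation"],
            labels=meta.get("labels"),
            p_values=None if meta.get("p_values") is None
            else np.asarray(meta["p_values"], dtype=float),
        )


def choose_k(m: int) -> int:
    """Component count policy: 100 when m > 100, otherwise floor(m / 2)."""
    if m < 4:
        raise ValueError(f"need at least 4 samples to decompose, got {m}")
    return 100 if m > 100 else m // 2


def run_sica(
    ds: ExpressionDataset,
    k: int,
    n_runs: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> Decomposition:
    """Stabilized ICA: pooled multi-run FastICA with icasso-style clustering.

    FastICA is run ``n_runs`` times on the row-centered matrix; the pooled
    metagenes are clustered into ``k`` clusters by average linkage on
    ``1 - |Pearson correlation|``. Each cluster contributes its centrotype
    metagene; stability is the mean within-cluster ``|correlation|``.
    Metasamples are refit by least squares so ``A @ S`` reconstructs the
    centered matrix up to residual. Orientation is ``none``.
    """
    if not ds.log_scale:
        raise ValueError(f"{ds.dataset_id}: decompose log-scale matrices only")
    n, m = ds.matrix.shape
    if k > min(n, m):
        raise ValueError(f"{ds.dataset_id}: k={k} exceeds min(n, m)={min(n, m)}")
    Xc = ds.matrix - ds.matrix.mean(axis=1, keepdims=True)
    rank = np.linalg.matrix_rank(Xc)
    if k > rank:
        raise ValueError(f"{ds.dataset_id}: k={k} exceeds rank {rank} of centered matrix")

    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)

    # whiten by SVD over genes (no extra centering, so sources stay in the
    # column space of the row-centered matrix and A @ S can reconstruct it)
    U, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    X_white = U[:, :k] * np.sqrt(n)

    pooled: list[np.ndarray] = []  # unit-norm metagenes, one per pooled component
    pooled_src: list[np.ndarray] = []
    n_converged = 0
    for rs in run_seeds:
        ica = FastICA(
            n_components=k,
            algorithm="parallel",
            fun="logcosh",
            whiten=False,
            max_iter=max_iter,
            tol=tol,
            random_state=int(rs),
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            # rows (genes) are the observations; sources = metagenes
            A = ica.fit_transform(X_white)  # (n, k)
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            n_converged += 1
        norms = np.linalg.norm(A, axis=0)
        norms[norms == 0] = 1.0
        for j in range(k):
            pooled.append(A[:, j] / norms[j])
            pooled_src.append(A[:, j])
    if n_converged == 0:
        raise RuntimeError(
            f"{ds.dataset_id}: FastICA failed to converge in all {n_runs} runs"
        )

    P = np.column_stack(pooled)  # (n, n_runs*k)
    C = np.abs(np.corrcoef(P, rowvar=False))
    np.fill_diagonal(C, 1.0)
    dissim = np.clip(1.0 - C, 0.0, None)
    dissim = (dissim + dissim.T) / 2.0
    Z = linkage(squareform(dissim, checks=False), method="average")
    clusters = fcluster(Z, t=k, criterion="maxclust")

    metagenes = np.empty((n, k))
    stability = np.empty(k)
    order = np.unique(clusters)
    if len(order) != k:  # pragma: no cover - maxclust guarantees k for distinct points
        raise RuntimeError(f"{ds.dataset_id}: clustering produced {len(order)} != k clusters")
    for out_idx, c in enumerate(order):
        members = np.where(clusters == c)[0]
        sub = C[np.ix_(members, members)]
        # centrotype: member maximizing total similarity to its cluster
        centro = members[int(np.argmax(sub.sum(axis=1)))]
        metagenes[:, out_idx] = pooled_src[centro]
        if len(members) == 1:
            stability[out_idx] = 1.0
        else:
            off = sub[~np.eye(len(members), dtype=bool)]
            stability[out_idx] = float(off.mean())

    # most stable components first
    rank_order = np.argsort(-stability, kind="stable")
    metagenes = metagenes[:, rank_order]
    stability = stability[rank_order]

    # refit metasamples by least squares: A @ S ~= Xc
    S, *_ = np.linalg.lstsq(metagenes, Xc, rcond=None)

    return Decomposition(
        dataset_id=ds.dataset_id,
        disease_group=ds.disease_group,
        metagenes=metagenes,
        metasamples=S,
        gene_ids=list(ds.gene_ids),
        sample_ids=list(ds.sample_ids),
        stability=stability,
        seed=seed,
        orientation="none",
        labels=list(ds.labels),
    )


def orient_long_tail(d: Decomposition) -> Decomposition:
    """Flip components so every metagene's weight skewness is >= 0."""
    if d.orientation != "none":
        raise ValueError(f"{d.dataset_id}: decomposition already oriented ({d.orientation})")
    A = d.metagenes.copy()
    S = d.metasamples.copy()
    for i in range(d.k):
        col = A[:, i]
        if np.allclose(col, col[0]):
            raise ValueError(f"{d.dataset_id}: component {i + 1} has zero-variance metagene")
        if skew(col) < 0:
            A[:, i] = -A[:, i]
            S[i, :] = -S[i, :]
    return replace(d, metagenes=A, metasamples=S, orientation="long_tail")


def rank_sum_statistic(case: np.ndarray, control: np.ndarray) -> float:
    """Centered rank-sum: sum of case midranks minus its null expectation.

    Positive iff case values rank higher than expected under exchangeability.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    pooled = np.concatenate([case, control])
    ranks = rankdata(pooled)
    n_case = len(case)
    expected = n_case * (len(pooled) + 1) / 2.0
    return float(ranks[:n_case].sum() - expected)


def orient_disease_pointing(
    d: Decomposition, labels: list[str] | None = None
) -> Decomposition:
    """Flip components so case metasample weights rank above controls.

    For each component the two-sample rank-sum statistic of case vs. control
    metasample weights (centered at its null expectation, midranks for ties)
    is computed; negative statistics flip both metagene and metasample. The
    per-component two-sided Wilcoxon p-value is stored.
    """
    if d.orientation != "none":
        raise ValueError(f"{d.dataset_id}: decomposition already oriented ({d.orientation})")
    labels = labels if labels is not None else d.labels
    if labels is None:
        raise ValueError(f"{d.dataset_id}: case/control labels required for disease pointing")
    if len(labels) != len(d.sample_ids):
        raise ValueError(f"{d.dataset_id}: label count does not match samples")
    case_mask = np.array([lab == "case" for lab in labels], dtype=bool)
    if not case_mask.any() or case_mask.all():
        raise ValueError(f"{d.dataset_id}: need both case and control samples")

    A = d.metagenes.copy()
    S = d.metasamples.copy()
    pvals = np.empty(d.k)
    for i in range(d.k):
        case_w = S[i, case_mask]
        ctrl_w = S[i, ~case_mask]
        stat = rank_sum_statistic(case_w, ctrl_w)
        if stat < 0:
            A[:, i] = -A[:, i]
            S[i, :] = -S[i, :]
        if np.all(case_w == case_w[0]) and np.all(ctrl_w == case_w[0]):
            pvals[i] = 1.0
        else:
            pvals[i] = mannwhitneyu(case_w, ctrl_w, alternative="two-sided").pvalue
    return replace(
        d,
        metagenes=A,
        metasamples=S,
        orientation="disease_pointing",
        labels=list(labels),
        p_values=pvals,
    )
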