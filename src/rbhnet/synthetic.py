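"""Multi-dataset expression generator with planted latent structure.

Each generated dataset is ``X = A @ S + E``: sparse Laplace metagenes
(super-Gaussian, as ICA assumes), Gaussian metasample activities with a
case/control mean shift, and i.i.d. Gaussian noise. Shared sources reuse one
gene support across all datasets (up to per-dataset jitter) and carry an
inverted case association between disease groups — the planted
inverse-comorbidity signal that should surface as cross-group negative RBH
edges grouped into one community per source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from rbhnet.decomposition import ComponentRef, Decomposition
from rbhnet.communities import CommunityPartition
from rbhnet.io_expression import ExpressionDataset
from rbhnet.rbh_network import RBHNetwork


@dataclass(frozen=True)
class GroupSpec:
    """One disease group: how many datasets, their size and case fraction."""

    label: str
    n_datasets: int
    n_samples: int
    case_fraction: float = 0.5


@dataclass
class FixtureConfig:
    """Parameters of the planted-structure generator."""

    n_genes: int = 1000
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("AD", 2, 40),
        GroupSpec("LC", 2, 40),
    )
    n_shared_sources: int = 3
    n_group_sources: int = 1
    n_private_sources: int = 1
    effect_size: float = 2.0  # case/control shift of source activity, in SD units
    sparsity: float = 0.10  # fraction of genes with nonzero Laplace weight
    noise_sd: float = 0.10
    jitter_sd: float = 0.05  # per-dataset Gaussian jitter on shared metagenes
    seed: int = 0

    def __post_init__(self) -> None:
        self.groups = tuple(
            g if isinstance(g, GroupSpec) else GroupSpec(*g) for g in self.groups
        )
        if self.n_genes <= 0 or not self.groups:
            raise ValueError("n_genes and groups must be positive/non-empty")
        for g in self.groups:
            if g.n_datasets <= 0 or g.n_samples <= 0:
                raise ValueError(f"group {g.label}: counts must be positive")
            if not 0 < g.case_fraction < 1:
                raise ValueError(f"group {g.label}: case fraction must be in (0, 1)")
        if min(self.n_shared_sources, 1) < 0 or self.n_shared_sources < 1:
            raise ValueError("need at least one shared source")
        if not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must be in (0, 1]")
        total = self.n_shared_sources + self.n_group_sources + self.n_private_sources
        min_m = min(g.n_samples for g in self.groups)
        if total > min_m // 2:
            raise ValueError(
                f"{total} sources exceed the identifiability bound "
                f"min(samples)/2 = {min_m // 2}"
            )

    @property
    def sources_per_dataset(self) -> int:
        return self.n_shared_sources + self.n_group_sources + self.n_private_sources


@dataclass
class FixtureTruth:
    """Ground truth of one generated collection.

    ``planted_metagenes[ds]`` has shape (n_genes, n_sources) with shared
    sources in columns ``0..n_shared-1``; ``group_signs[group][s]`` is the
    case-association sign of shared source ``s`` in that group;
    ``expected_neg_edges`` lists the cross-group component pairs that should
    appear as negative RBHs; ``source_of[(ds, comp_idx)]`` maps planted
    components (1-based) of shared sources to their source id.
    """

    config: FixtureConfig
    planted_metagenes: dict[str, np.ndarray]
    planted_metasamples: dict[str, np.ndarray]
    dataset_groups: dict[str, str]
    group_signs: dict[str, list[int]]
    expected_neg_edges: set[tuple[tuple[str, int], tuple[str, int]]]
    source_of: dict[tuple[str, int], int]

    def expected_community_of(self) -> dict[tuple[str, int], int]:
        """Planted grouping: shared-source id per planted component."""
        return dict(self.source_of)


def generate(config: FixtureConfig) -> tuple[list[ExpressionDataset], FixtureTruth]:
    """Generate the expression collection plus its ground truth.

    Deterministic under ``config.seed``. Matrices are produced directly on
    the (conceptually log2) analysis scale, so ``log_scale`` is set.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_sh, n_gr, n_pr = (
        config.n_shared_sources, config.n_group_sources, config.n_private_sources,
    )
    n_src = config.sources_per_dataset
    support_size = max(1, int(round(config.sparsity * n)))

    # shared sources: one base Laplace metagene each, reused by every dataset
    shared_bases = []
    for _ in range(n_sh):
        support = rng.choice(n, size=support_size, replace=False)
        base = np.zeros(n)
        base[support] = rng.laplace(scale=1.0, size=support_size)
        shared_bases.append(base)

    # per-group sources: one base per (group, source)
    group_bases: dict[str, list[np.ndarray]] = {}
    for g in config.groups:
        bases = []
        for _ in range(n_gr):
            support = rng.choice(n, size=support_size, replace=False)
            base = np.zeros(n)
            base[support] = rng.laplace(scale=1.0, size=support_size)
            bases.append(base)
        group_bases[g.label] = bases

    # inverse comorbidity: alternate the case-association sign across groups
    group_signs = {
        g.label: [(+1 if gi % 2 == 0 else -1) for _ in range(n_sh)]
        for gi, g in enumerate(config.groups)
    }

    datasets: list[ExpressionDataset] = []
    planted_A: dict[str, np.ndarray] = {}
    planted_S: dict[str, np.ndarray] = {}
    dataset_groups: dict[str, str] = {}
    source_of: dict[tuple[str, int], int] = {}

    for g in config.groups:
        for di in range(g.n_datasets):
            ds_id = f"{g.label}{di + 1}"
            m = g.n_samples
            n_case = max(1, min(m - 1, int(round(g.case_fraction * m))))
            labels = ["case"] * n_case + ["control"] * (m - n_case)

            A = np.empty((n, n_src))
            S = np.empty((n_src, m))
            col = 0
            for s in range(n_sh):
                A[:, col] = shared_bases[s] + rng.normal(0.0, config.jitter_sd, size=n)
                act = rng.normal(0.0, 1.0, size=m)
                act[:n_case] += group_signs[g.label][s] * config.effect_size
                S[col] = act
                source_of[(ds_id, col + 1)] = s
                col += 1
            for s in range(n_gr):
                A[:, col] = group_bases[g.label][s] + rng.normal(
                    0.0, config.jitter_sd, size=n
                )
                act = rng.normal(0.0, 1.0, size=m)
                act[:n_case] += config.effect_size
                S[col] = act
                col += 1
            for _ in range(n_pr):
                support = rng.choice(n, size=support_size, replace=False)
                base = np.zeros(n)
                base[support] = rng.laplace(scale=1.0, size=support_size)
                A[:, col] = base
                S[col] = rng.normal(0.0, 1.0, size=m)
                col += 1

            X = A @ S + rng.normal(0.0, config.noise_sd, size=(n, m))
            datasets.append(
                ExpressionDataset(
                    dataset_id=ds_id,
                    disease_group=g.label,
                    matrix=X,
                    gene_ids=[f"G{i + 1:05d}" for i in range(n)],
                    sample_ids=[f"{ds_id}_s{j + 1}" for j in range(m)],
                    labels=labels,
                    log_scale=True,
                )
            )
            planted_A[ds_id] = A
            planted_S[ds_id] = S
            dataset_groups[ds_id] = g.label

    expected_neg: set[tuple[tuple[str, int], tuple[str, int]]] = set()
    ds_ids = list(dataset_groups)
    for i, da in enumerate(ds_ids):
        for db in ds_ids[i + 1:]:
            ga, gb = dataset_groups[da], dataset_groups[db]
            if ga == gb:
                continue
            for s in range(n_sh):
                if group_signs[ga][s] != group_signs[gb][s]:
                    expected_neg.add(((da, s + 1), (db, s + 1)))

    truth = FixtureTruth(
        config=config,
        planted_metagenes=planted_A,
        planted_metasamples=planted_S,
        dataset_groups=dataset_groups,
        group_signs=group_signs,
        expected_neg_edges=expected_neg,
        source_of=source_of,
    )
    return datasets, truth


def match_components(
    truth: FixtureTruth, decomps: list[Decomposition]
) -> tuple[dict[tuple[str, int], tuple[str, int]], float]:
    """Assign each planted source to the recovered component best matching it.

    Returns the mapping ``(dataset, planted 1-based idx) -> (dataset,
    recovered 1-based idx)`` maximizing total ``|Spearman|`` (Hungarian
    assignment per dataset), plus the mean matched ``|Spearman|``.
    """
    mapping: dict[tuple[str, int], tuple[str, int]] = {}
    rhos: list[float] = []
    dmap = {d.dataset_id: d for d in decomps}
    for ds_id, A_true in truth.planted_metagenes.items():
        if ds_id not in dmap:
            raise ValueError(f"no decomposition for generated dataset {ds_id!r}")
        A_rec = dmap[ds_id].metagenes
        n_t, n_r = A_true.shape[1], A_rec.shape[1]
        C = np.zeros((n_t, n_r))
        for i in range(n_t):
            for j in range(n_r):
                C[i, j] = abs(spearmanr(A_true[:, i], A_rec[:, j]).statistic)
        rows, cols = linear_sum_assignment(-C)
        for i, j in zip(rows, cols):
            mapping[(ds_id, i + 1)] = (ds_id, j + 1)
            rhos.append(C[i, j])
    return mapping, float(np.mean(rhos)) if rhos else 0.0


def score_recovery(
    truth: FixtureTruth,
    net: RBHNetwork,
    part: CommunityPartition,
    decomps: list[Decomposition],
) -> dict:
    """Precision/recall of planted cross-group negative edges, mean matched
    ``|Spearman|``, and ARI between planted and recovered communities."""
    gen_ids = set(truth.dataset_groups)
    net_ids = {n.dataset_id for n in net.nodes}
    if not gen_ids <= net_ids:
        raise ValueError(
            f"network is missing generated datasets: {sorted(gen_ids - net_ids)}"
        )
    mapping, mean_rho = match_components(truth, decomps)

    expected = {
        frozenset((mapping[a], mapping[b])) for a, b in truth.expected_neg_edges
    }
    actual = set()
    for e in net.edges:
        if e.sign != "-":
            continue
        a, b = e.endpoint_a, e.endpoint_b
        if a.disease_group == b.disease_group:
            continue
        actual.add(frozenset(((a.dataset_id, a.component_index),
                              (b.dataset_id, b.component_index))))
    tp = len(expected & actual)
    precision = tp / len(actual) if actual else 0.0
    recall = tp / len(expected) if expected else 1.0

    planted_comm = truth.expected_community_of()
    node_comm = {
        (n.dataset_id, n.component_index): i
        for i, c in enumerate(part.communities) for n in c
    }
    pairs = [
        (planted_comm[key], node_comm[mapping[key]])
        for key in planted_comm
        if key in mapping and mapping[key] in node_comm
    ]
    if pairs:
        true_lab, rec_lab = zip(*pairs)
        ari = float(adjusted_rand_score(true_lab, rec_lab))
        coverage = len(pairs) / len(planted_comm)
        # planted components absent from the clustered subnetwork count
        # against recovery: scale ARI by coverage when incomplete
        ari = ari if coverage == 1.0 else ari * coverage
    else:
        ari = 0.0
    return {
        "precision": precision,
        "recall": recall,
        "mean_matched_abs_spearman": mean_rho,
        "ari": ari,
        "n_expected_neg_edges": len(expected),
        "n_recovered_neg_edges": len(actual),
    }


def write_fixture_collection(
    datasets: list[ExpressionDataset],
    truth: FixtureTruth,
    directory: str | Path,
) -> Path:
    """Write fixtures as TSV matrices + labels + a YAML registry + truth JSON.

    Returns the registry path, ready for the CLI pipeline.
    """
    import yaml

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    entries = []
    for ds in datasets:
        mpath = d / f"{ds.dataset_id}.expr.tsv"
        lpath = d / f"{ds.dataset_id}.labels.tsv"
        ds.to_frame().to_csv(mpath, sep="\t", index_label="gene")
        with open(lpath, "w") as fh:
            fh.write("sample_id\tlabel\n")
            for s, lab in zip(ds.sample_ids, ds.labels):
                fh.write(f"{s}\t{lab}\n")
        entries.append(
            {
                "dataset_id": ds.dataset_id,
                "disease_group": ds.disease_group,
                "matrix": mpath.name,
                "labels": lpath.name,
                "log_scale": bool(ds.log_scale),
                "filter_zeros": False,
                "log2": False,
            }
        )
    registry = d / "registry.yaml"
    registry.write_text(yaml.safe_dump({"datasets": entries}, sort_keys=False))
    truth_json = {
        "dataset_groups": truth.dataset_groups,
        "group_signs": truth.group_signs,
        "expected_neg_edges": sorted(
            [sorted(map(list, pair)) for pair in truth.expected_neg_edges]
        ),
        "source_of": {f"{ds}:{i}": s for (ds, i), s in truth.source_of.items()},
        "seed": truth.config.seed,
    }
    (d / "truth.json").write_text(json.dumps(truth_json, indent=2))
    return registry
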