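import numpy as np
import pytest

from rbhnet.decomposition import (
    Decomposition,
    orient_disease_pointing,
    orient_long_tail,
    run_sica,
)
from rbhnet.io_expression import ExpressionDataset
from rbhnet.rbh_network import build_network
from rbhnet.communities import extract_subnetwork, mcl
from rbhnet.synthetic import FixtureConfig, GroupSpec, generate


def make_dataset(
    matrix,
    dataset_id="d1",
    disease_group="AD",
    labels=None,
    gene_ids=None,
    sample_ids=None,
    log_scale=False,
    subtype=None,
):
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    if labels is None:
        labels = ["case"] * (m // 2) + ["control"] * (m - m // 2)
    return ExpressionDataset(
        dataset_id=dataset_id,
        disease_group=disease_group,
        matrix=matrix,
        gene_ids=gene_ids or [f"G{i}" for i in range(n)],
        sample_ids=sample_ids or [f"s{j}" for j in range(m)],
        labels=labels,
        subtype=subtype,
        log_scale=log_scale,
    )


def make_decomposition(
    metagenes,
    dataset_id="d1",
    disease_group="AD",
    metasamples=None,
    labels=None,
    gene_ids=None,
    orientation="none",
    p_values=None,
    seed=0,
):
    """Wrap raw arrays in a Decomposition for network-level tests."""
    A = np.asarray(metagenes, dtype=float)
    n, k = A.shape
    if metasamples is None:
        metasamples = np.zeros((k, max(k, 2)))
    S = np.asarray(metasamples, dtype=float)
    m = S.shape[1]
    if labels is None:
        labels = ["case"] * (m // 2) + ["control"] * (m - m // 2)
    return Decomposition(
        dataset_id=dataset_id,
        disease_group=disease_group,
        metagenes=A,
        metasamples=S,
        gene_ids=gene_ids or [f"G{i}" for i in range(n)],
        sample_ids=[f"s{j}" for j in range(m)],
        stability=np.ones(k),
        seed=seed,
        orientation=orientation,
        labels=labels,
        p_values=p_values,
    )


SMALL_CONFIG = FixtureConfig(
    n_genes=400,
    groups=(GroupSpec("AD", 2, 30), GroupSpec("LC", 2, 30)),
    n_shared_sources=3,
    n_group_sources=1,
    n_private_sources=1,
    effect_size=2.0,
    noise_sd=0.05,
    seed=7,
)


@pytest.fixture(scope="session")
def small_collection():
    """Generated datasets plus ground truth for the small default config."""
    return generate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_pipeline(small_collection):
    """Full pipeline artifacts on the small fixture, both orientations."""
    datasets, truth = small_collection
    rng = np.random.default_rng(11)
    unoriented = [
        run_sica(ds, k=5, n_runs=8, seed=int(rng.integers(2**31 - 1)))
        for ds in datasets
    ]
    dp = [orient_disease_pointing(d) for d in unoriented]
    lt = [orient_long_tail(d) for d in unoriented]
    net_dp = build_network(dp, min_shared_genes=100)
    net_lt = build_network(lt, min_shared_genes=100)
    sub = extract_subnetwork(net_dp, "AD", "LC", "-")
    part = mcl(sub)
    return {
        "datasets": datasets,
        "truth": truth,
        "unoriented": unoriented,
        "decomps_dp": dp,
        "decomps_lt": lt,
        "net_dp": net_dp,
        "net_lt": net_lt,
        "subnetwork": sub,
        "partition": part,
    }
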