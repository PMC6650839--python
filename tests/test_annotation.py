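from itertools import combinations
from math import comb

import numpy as np
import pytest

from rbhnet.annotation import (
    ConsensusMetagene,
    SignatureCollection,
    consensus_metagene,
    enrich,
    match_external_metagenes,
    read_gmt,
    subtype_association,
    top_genes,
)
from rbhnet.communities import CommunityPartition, Subnetwork
from rbhnet.decomposition import ComponentRef
from rbhnet.rbh_network import RBHEdge

from conftest import make_decomposition


def ref(ds, idx, group="LC"):
    return ComponentRef(ds, idx, group)


def edge(a, b, w):
    return RBHEdge(a, b, "+" if w > 0 else "-", w, 100)


def hypergeom_tail_bruteforce(N, K, n, x):
    """Upper-tail P(X >= x) by direct summation of binomial products."""
    total = comb(N, n)
    s = 0
    for k in range(x, min(K, n) + 1):
        s += comb(K, k) * comb(N - K, n - k)
    return s / total


class TestReadGMT:
    def test_two_lines(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text(
            "SIG_A\tdesc\tTP53\tEGFR\tMYC\n"
            "SIG_B\tdesc\tkras\tBRAF\n"
        )
        coll = read_gmt(str(p))
        assert len(coll) == 2
        assert coll.signatures["SIG_A"] == {"TP53", "EGFR", "MYC"}
        assert coll.signatures["SIG_B"] == {"KRAS", "BRAF"}  # upper-cased

    def test_duplicate_gene_deduplicated(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SIG\tdesc\tTP53\tTP53\tMYC\n")
        coll = read_gmt(str(p))
        assert coll.signatures["SIG"] == {"TP53", "MYC"}

    def test_short_line_errors_with_lineno(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SIG_A\tdesc\tTP53\nBAD_LINE\tonly_desc\n")
        with pytest.raises(ValueError, match=":2:"):
            read_gmt(str(p))

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_gmt(str(p))


class TestConsensusMetagene:
    def _community(self, vecs, weights_between, groups=None):
        """Build decomps d0..dn with 1 component each, chained by given edges."""
        decomps = [
            make_decomposition(np.asarray(v).reshape(-1, 1), dataset_id=f"d{i}",
                               disease_group=(groups[i] if groups else "LC"))
            for i, v in enumerate(vecs)
        ]
        members = {ref(f"d{i}", 1, groups[i] if groups else "LC")
                   for i in range(len(vecs))}
        edges = {
            edge(ref(f"d{a}", 1, groups[a] if groups else "LC"),
                 ref(f"d{b}", 1, groups[b] if groups else "LC"), w)
            for a, b, w in weights_between
        }
        sub = Subnetwork(nodes=members, edges=edges)
        return members, decomps, sub

    def test_negated_pair_aligns_to_reference(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=20)
        members, decomps, sub = self._community([v, -v], [(0, 1, -1.0)])
        cm = consensus_metagene(members, decomps, sub, "LC")
        np.testing.assert_allclose(cm.weights, v)

    def test_identical_pair_plus_edge(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=20)
        members, decomps, sub = self._community([v, v], [(0, 1, 1.0)])
        cm = consensus_metagene(members, decomps, sub, "LC")
        np.testing.assert_allclose(cm.weights, v)

    def test_three_member_mixed_signs_hand_oracle(self):
        rng = np.random.default_rng(2)
        v0, v1, v2 = rng.normal(size=(3, 20))
        # chain d0 -(+)- d1 -(-)- d2: aligned = v0, v1, -v2
        members, decomps, sub = self._community(
            [v0, v1, v2], [(0, 1, 0.8), (1, 2, -0.7)]
        )
        cm = consensus_metagene(members, decomps, sub, "LC")
        np.testing.assert_allclose(cm.weights, (v0 + v1 - v2) / 3, atol=1e-12)

    def test_disconnected_errors(self):
        rng = np.random.default_rng(3)
        vecs = rng.normal(size=(3, 20))
        members, decomps, sub = self._community(list(vecs), [(0, 1, 0.5)])
        with pytest.raises(ValueError, match="disconnected"):
            consensus_metagene(members, decomps, sub, "LC")

    def test_reference_invariance_up_to_global_sign(self):
        rng = np.random.default_rng(4)
        v0, v1, v2 = rng.normal(size=(3, 30))
        members, decomps, sub = self._community(
            [v0, v1, v2], [(0, 1, -0.9), (1, 2, 0.6), (0, 2, -0.5)],
            groups=["LC", "AD", "LC"],
        )
        cm_lc = consensus_metagene(members, decomps, sub, "LC")
        cm_ad = consensus_metagene(members, decomps, sub, "AD")
        ratio = cm_ad.weights / cm_lc.weights
        assert np.allclose(ratio, 1.0) or np.allclose(ratio, -1.0)

    def test_union_of_gene_sets(self):
        # members defined on overlapping but unequal gene sets
        rng = np.random.default_rng(5)
        d0 = make_decomposition(rng.normal(size=(4, 1)), dataset_id="d0",
                                disease_group="LC",
                                gene_ids=["A", "B", "C", "D"])
        d1 = make_decomposition(rng.normal(size=(4, 1)), dataset_id="d1",
                                disease_group="LC",
                                gene_ids=["B", "C", "D", "E"])
        members = {ref("d0", 1), ref("d1", 1)}
        sub = Subnetwork(nodes=members,
                         edges={edge(ref("d0", 1), ref("d1", 1), 0.9)})
        cm = consensus_metagene(members, [d0, d1], sub, "LC")
        assert set(cm.gene_ids) == {"A", "B", "C", "D", "E"}
        i0 = {g: w for g, w in zip(d0.gene_ids, d0.metagenes[:, 0])}
        i1 = {g: w for g, w in zip(d1.gene_ids, d1.metagenes[:, 0])}
        w = dict(zip(cm.gene_ids, cm.weights))
        assert w["A"] == pytest.approx(i0["A"])
        assert w["E"] == pytest.approx(i1["E"])
        assert w["C"] == pytest.approx((i0["C"] + i1["C"]) / 2)


class TestTopGenes:
    def test_outlier_in_up(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=1000)
        w = np.append(w, 10 * w.std())
        cm = ConsensusMetagene(0, [f"G{i}" for i in range(1001)], w, 2, "LC")
        up, down = top_genes(cm)
        assert "G1000" in up

    def test_no_extreme_weights_empty(self):
        w = np.linspace(-1, 1, 100)
        cm = ConsensusMetagene(0, [f"G{i}" for i in range(100)], w, 2, "LC")
        up, down = top_genes(cm)
        assert up == set() and down == set()

    def test_manual_thresholding_twenty_weights(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=20)
        w[3], w[17] = 8.0, -9.0
        cm = ConsensusMetagene(0, [f"G{i}" for i in range(20)], w, 2, "LC")
        sd = np.std(w, ddof=1)
        exp_up = {f"G{i}" for i in range(20) if w[i] > 3 * sd}
        exp_down = {f"G{i}" for i in range(20) if w[i] < -3 * sd}
        up, down = top_genes(cm)
        assert up == exp_up and down == exp_down

    def test_zero_sd_errors(self):
        cm = ConsensusMetagene(0, [f"G{i}" for i in range(12)], np.ones(12), 1, "LC")
        with pytest.raises(ValueError, match="zero standard deviation"):
            top_genes(cm)


class TestEnrich:
    def test_full_overlap_matches_bruteforce(self):
        universe = {f"G{i}" for i in range(100)}
        sig = {f"G{i}" for i in range(10)}
        coll = SignatureCollection("c", {"SIG": set(sig)})
        res = enrich(set(sig), coll, universe)
        expected = hypergeom_tail_bruteforce(100, 10, 10, 10)
        assert res[0].p_raw == pytest.approx(expected, abs=1e-12)

    def test_disjoint_overlap_p_one(self):
        universe = {f"G{i}" for i in range(50)}
        coll = SignatureCollection("c", {"SIG": {f"G{i}" for i in range(5)}})
        res = enrich({f"G{i}" for i in range(40, 45)}, coll, universe)
        assert res[0].overlap == 0
        assert res[0].p_raw == pytest.approx(1.0)

    def test_printed_example(self):
        # universe 100, set 10, signature 10, overlap 5
        universe = {f"G{i}" for i in range(100)}
        sig = {f"G{i}" for i in range(10)}
        gene_set = {f"G{i}" for i in range(5)} | {f"G{i}" for i in range(90, 95)}
        coll = SignatureCollection("c", {"SIG": sig})
        res = enrich(gene_set, coll, universe)
        expected = sum(
            comb(10, x) * comb(90, 10 - x) for x in range(5, 11)
        ) / comb(100, 10)
        assert res[0].p_raw == pytest.approx(expected, abs=1e-12)

    def test_bonferroni_monotone_and_capped(self):
        rng = np.random.default_rng(0)
        universe = {f"G{i}" for i in range(60)}
        sigs = {
            f"S{j}": set(rng.choice(sorted(universe), size=8, replace=False))
            for j in range(5)
        }
        coll = SignatureCollection("c", sigs)
        gene_set = set(rng.choice(sorted(universe), size=10, replace=False))
        for r in enrich(gene_set, coll, universe):
            assert r.p_adjusted >= r.p_raw
            assert r.p_adjusted <= 1.0
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 5))

    def test_planted_signature_minimal_p(self):
        rng = np.random.default_rng(1)
        universe = {f"G{i}" for i in range(200)}
        planted = {f"G{i}" for i in range(15)}
        decoys = {
            f"D{j}": set(rng.choice(sorted(universe), size=15, replace=False))
            for j in range(8)
        }
        coll = SignatureCollection("c", {"PLANTED": planted, **decoys})
        res = enrich(set(planted), coll, universe)
        assert res[0].signature == "PLANTED"
        assert res[0].p_adjusted == min(r.p_adjusted for r in res)

    def test_errors(self):
        coll = SignatureCollection("c", {"S": {"A"}})
        with pytest.raises(ValueError, match="universe"):
            enrich({"A"}, coll, set())
        with pytest.raises(ValueError, match="empty gene set"):
            enrich(set(), coll, {"A"})
        with pytest.raises(ValueError, match="subset"):
            enrich({"Z"}, coll, {"A"})


class TestSubtypeAssociation:
    def test_separated_groups_exact_p(self):
        # subtype strictly above the rest, n1=n2=5: two-sided p = 2/C(10,5)
        weights = np.array([10, 11, 12, 13, 14, 1, 2, 3, 4, 5], dtype=float)
        subtypes = ["A"] * 5 + ["B"] * 5
        res = subtype_association(weights, subtypes)
        expected = 2 / comb(10, 5)
        assert res["A"][0] == pytest.approx(expected, abs=1e-12)
        assert res["B"][0] == pytest.approx(expected, abs=1e-12)

    def test_identical_weights_p_one(self):
        res = subtype_association(np.ones(8), ["A"] * 4 + ["B"] * 4)
        assert res["A"][0] == pytest.approx(1.0)

    def test_bonferroni_three_subtypes(self):
        rng = np.random.default_rng(0)
        weights = rng.normal(size=12)
        subtypes = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        res = subtype_association(weights, subtypes)
        for lv, (p, padj) in res.items():
            assert padj == pytest.approx(min(1.0, 3 * p))

    def test_exact_permutation_oracle(self):
        # enumerate all case assignments of 4+4 samples, no ties
        rng = np.random.default_rng(1)
        weights = rng.permutation(np.arange(1.0, 9.0))
        subtypes = ["A"] * 4 + ["B"] * 4
        got = subtype_association(weights, subtypes)["A"][0]
        ranks = np.argsort(np.argsort(weights)) + 1
        obs = ranks[:4].sum()
        null = [
            sum(c) for c in combinations(range(1, 9), 4)
        ]
        mean = np.mean(null)
        p_exact = np.mean([abs(x - mean) >= abs(obs - mean) - 1e-9 for x in null])
        assert got == pytest.approx(p_exact, abs=1e-9)

    def test_single_subtype_errors(self):
        with pytest.raises(ValueError, match="two subtypes"):
            subtype_association(np.ones(4), ["A"] * 4)
        with pytest.raises(ValueError, match="fewer than 2"):
            subtype_association(np.ones(4), ["A", "A", "A", "B"])


class TestMatchExternalMetagenes:
    def _subnetwork(self, decomps):
        import pandas as pd
        a, b = decomps
        members = {ref(a.dataset_id, 1, "AD"), ref(b.dataset_id, 1, "LC")}
        sub = Subnetwork(
            nodes=members,
            edges={edge(ref(a.dataset_id, 1, "AD"), ref(b.dataset_id, 1, "LC"),
                        -0.9)},
        )
        part = CommunityPartition(communities=[members], inflation=2.0)
        return sub, part

    def test_matching_external_counts(self):
        import pandas as pd
        rng = np.random.default_rng(0)
        A = rng.normal(size=(60, 2))
        da = make_decomposition(A, dataset_id="ad1", disease_group="AD",
                                gene_ids=[f"G{i}" for i in range(60)])
        db = make_decomposition(A + rng.normal(0, 0.1, size=A.shape),
                                dataset_id="lc1", disease_group="LC",
                                gene_ids=[f"G{i}" for i in range(60)])
        sub, part = self._subnetwork([da, db])
        ext = pd.DataFrame(A[:, :1], index=[f"G{i}" for i in range(60)])
        counts = match_external_metagenes(
            {"CANCER1": ext}, [da, db], sub, part, min_shared_genes=30,
        )
        assert counts[0] >= 1

    def test_noise_external_no_hit(self):
        import pandas as pd
        rng = np.random.default_rng(1)
        A = rng.normal(size=(200, 2))
        da = make_decomposition(A, dataset_id="ad1", disease_group="AD",
                                gene_ids=[f"G{i}" for i in range(200)])
        db = make_decomposition(A, dataset_id="lc1", disease_group="LC",
                                gene_ids=[f"G{i}" for i in range(200)])
        sub, part = self._subnetwork([da, db])
        noise = pd.DataFrame(rng.normal(size=(200, 3)),
                             index=[f"G{i}" for i in range(200)])
        counts = match_external_metagenes(
            {"NOISE": noise}, [da, db], sub, part,
            min_shared_genes=100, rho_cutoff=0.3,
        )
        assert counts[0] == 0

    def test_two_cancers_both_match(self):
        import pandas as pd
        rng = np.random.default_rng(2)
        A = rng.normal(size=(60, 2))
        da = make_decomposition(A, dataset_id="ad1", disease_group="AD",
                                gene_ids=[f"G{i}" for i in range(60)])
        db = make_decomposition(A, dataset_id="lc1", disease_group="LC",
                                gene_ids=[f"G{i}" for i in range(60)])
        sub, part = self._subnetwork([da, db])
        ext = pd.DataFrame(A[:, :1], index=[f"G{i}" for i in range(60)])
        counts = match_external_metagenes(
            {"C1": ext, "C2": ext.copy() * -1}, [da, db], sub, part,
            min_shared_genes=30,
        )
        assert counts[0] == 2

    def test_low_overlap_skipped(self):
        import pandas as pd
        rng = np.random.default_rng(3)
        A = rng.normal(size=(60, 2))
        da = make_decomposition(A, dataset_id="ad1", disease_group="AD",
                                gene_ids=[f"G{i}" for i in range(60)])
        db = make_decomposition(A, dataset_id="lc1", disease_group="LC",
                                gene_ids=[f"G{i}" for i in range(60)])
        sub, part = self._subnetwork([da, db])
        ext = pd.DataFrame(rng.normal(size=(60, 1)),
                           index=[f"X{i}" for i in range(60)])
        counts = match_external_metagenes(
            {"ALIEN": ext}, [da, db], sub, part, min_shared_genes=30,
        )
        assert counts[0] == 0
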