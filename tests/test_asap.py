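"""Barcode-gap partitioning: merges, panmixia test, candidate ranking."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from delimpy import Alignment, asap_delimit, panmixia_pvalue, single_linkage_merges
from delimpy.asap import AsapPartitioner, asap_partition
from delimpy.seqdata import DistanceMatrix
from conftest import random_distance_matrix


def components_at(dm, t):
    """Oracle: connected components of the graph joining pairs <= t apart."""
    g = nx.Graph()
    g.add_nodes_from(dm.labels)
    n = dm.n
    for i in range(n):
        for j in range(i + 1, n):
            if dm.D[i, j] <= t:
                g.add_edge(dm.labels[i], dm.labels[j])
    return {frozenset(c) for c in nx.connected_components(g)}


def _dm_two_pairs():
    # two tight pairs (0.001 apart) separated by 0.05
    labels = ["a1", "a2", "b1", "b2"]
    D = np.full((4, 4), 0.05)
    D[0, 1] = D[1, 0] = 0.001
    D[2, 3] = D[3, 2] = 0.001
    np.fill_diagonal(D, 0)
    return DistanceMatrix(labels, D, "p")


class TestMerges:
    def test_single_label_no_merges(self):
        dm = DistanceMatrix(["only"], np.zeros((1, 1)), "p")
        assert single_linkage_merges(dm) == []

    def test_two_pairs_merge_sequence(self):
        events = single_linkage_merges(_dm_two_pairs())
        assert [e.d_merge for e in events] == pytest.approx([0.001, 0.001, 0.05])
        assert {frozenset(g) for g in events[1].groups_after} == {
            frozenset({"a1", "a2"}), frozenset({"b1", "b2"})
        }

    def test_equal_distances_all_merge_at_common_value(self):
        D = np.full((5, 5), 0.3)
        np.fill_diagonal(D, 0)
        dm = DistanceMatrix(list("abcde"), D, "p")
        events = single_linkage_merges(dm)
        assert all(e.d_merge == pytest.approx(0.3) for e in events)

    def test_merge_states_equal_connected_components(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            dm = random_distance_matrix(12, rng)
            for ev in single_linkage_merges(dm):
                assert {frozenset(g) for g in ev.groups_after} == components_at(
                    dm, ev.d_merge
                )


class TestPanmixia:
    def test_uniform_distances_give_p_one(self):
        D = np.full((6, 6), 0.2)
        np.fill_diagonal(D, 0)
        dm = DistanceMatrix(list("abcdef"), D, "p")
        p = panmixia_pvalue(dm, frozenset("abc"), frozenset("def"), seed=1)
        assert p == 1.0

    def test_two_singletons_convention(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.1, 0]]), "p")
        assert panmixia_pvalue(dm, frozenset("a"), frozenset("b")) == 1.0

    def test_exhaustive_matches_enumeration_oracle(self):
        # 3+3 labels, between-distances 10x within
        labels = list("abcdef")
        D = np.full((6, 6), 0.5)
        within = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]
        for i, j in within:
            D[i, j] = D[j, i] = 0.05
        np.fill_diagonal(D, 0)
        dm = DistanceMatrix(labels, D, "p")
        p = panmixia_pvalue(dm, frozenset("abc"), frozenset("def"), seed=0)

        # oracle: enumerate all C(6,3)/2 = 10 distinct splits directly
        def stat(side):
            side = set(side)
            betw = [D[i, j] for i in range(6) for j in range(6)
                    if i < j and (i in side) != (j in side)]
            with_ = [D[i, j] for i in range(6) for j in range(6)
                     if i < j and (i in side) == (j in side)]
            return np.mean(betw) - np.mean(with_)

        obs = stat({0, 1, 2})
        splits = [c for c in itertools.combinations(range(6), 3) if 0 in c]
        assert len(splits) == 10
        expect = sum(stat(c) >= obs - 1e-12 for c in splits) / 10
        assert p == pytest.approx(expect)
        assert p == pytest.approx(0.1)

    def test_exhaustive_independent_of_seed(self):
        dm = _dm_two_pairs()
        args = (dm, frozenset({"a1", "a2"}), frozenset({"b1", "b2"}))
        assert panmixia_pvalue(*args, seed=1) == panmixia_pvalue(*args, seed=999)

    def test_monte_carlo_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        dm = random_distance_matrix(12, rng)
        a = frozenset(dm.labels[:6])
        b = frozenset(dm.labels[6:])
        p1 = panmixia_pvalue(dm, a, b, n_perm=199, seed=7)
        p2 = panmixia_pvalue(dm, a, b, n_perm=199, seed=7)
        assert p1 == p2


def _two_cluster_alignment(rng=None, n_per=4, L=500, intra=0.001, inter=0.05):
    """Two clusters of sequences with controlled intra/inter divergence."""
    rng = rng or np.random.default_rng(0)
    base = rng.choice(list("ACGT"), L)
    other = base.copy()
    k = max(1, int(inter * L))
    pos = rng.choice(L, k, replace=False)
    for p in pos:
        other[p] = "ACGT"[("ACGT".index(other[p]) + 2) % 4]
    ids, seqs = [], []
    for name, tmpl in [("x", base), ("y", other)]:
        for i in range(n_per):
            s = tmpl.copy()
            nmut = rng.poisson(intra * L)
            for p in rng.choice(L, nmut, replace=False):
                s[p] = "ACGT"[("ACGT".index(s[p]) + 1) % 4]
            ids.append(f"{name}{i}")
            seqs.append("".join(s))
    return Alignment(ids, seqs)


class TestDelimit:
    def test_identical_sequences_single_candidate(self):
        aln = Alignment(["a", "b", "c"], ["ACGT" * 5] * 3)
        res = asap_delimit(aln, models=("p",), n_perm=99)
        assert len(res["p"]) == 1
        assert res["p"][0].n_species == 1

    def test_two_cluster_alignment_best_is_two_species(self):
        aln = _two_cluster_alignment()
        res = asap_delimit(aln, models=("K80",), n_perm=199, seed=3)
        best = res["K80"][0]
        assert best.n_species == 2
        assert {frozenset(g) for g in best.groups} == {
            frozenset({"x0", "x1", "x2", "x3"}),
            frozenset({"y0", "y1", "y2", "y3"}),
        }
        # reported threshold lies inside the barcode gap
        assert 0.005 < best.threshold_dist < 0.06

    def test_candidate_schema_and_ordering(self):
        aln = _two_cluster_alignment()
        res = asap_delimit(aln, models=("p", "JC69", "K80"), n_perm=99, seed=1)
        for model, cands in res.items():
            order = [(not c.above_reference, c.asap_score) for c in cands]
            assert order == sorted(order)
            for c in cands:
                d = c.to_dict()
                for key in ("asap_score", "p_value", "W", "threshold_dist"):
                    assert key in d
                assert c.asap_score >= 1.0
                assert 0 <= c.p_value <= 1
                assert c.W >= 0
                assert c.d_cur <= c.d_next + 1e-15

    def test_thresholds_increase_as_partitions_coarsen(self):
        rng = np.random.default_rng(23)
        dm = random_distance_matrix(10, rng)
        cands = asap_partition(dm, n_perm=99, seed=0)
        by_n = sorted(cands, key=lambda c: -c.n_species)
        ds = [c.d_cur for c in by_n]
        ns = [c.n_species for c in by_n]
        assert ds == sorted(ds)
        assert ns == sorted(ns, reverse=True)
        assert all(a > b for a, b in zip(ns, ns[1:]))

    def test_candidates_equal_connected_components(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            dm = random_distance_matrix(12, rng)
            for c in asap_partition(dm, n_perm=99, seed=0):
                thr = c.d_cur
                assert {frozenset(g) for g in c.groups} == components_at(dm, thr)

    def test_score_invariant_to_relabeling(self):
        aln = _two_cluster_alignment(n_per=3)
        res1 = asap_delimit(aln, models=("p",), n_perm=999, seed=5)
        perm = [4, 2, 0, 5, 1, 3]
        aln2 = Alignment([aln.ids[i] for i in perm], [aln.seqs[i] for i in perm])
        res2 = asap_delimit(aln2, models=("p",), n_perm=999, seed=5)
        s1 = [(c.n_species, c.asap_score) for c in res1["p"]]
        s2 = [(c.n_species, c.asap_score) for c in res2["p"]]
        assert s1 == s2

    def test_reference_threshold_flag(self):
        aln = _two_cluster_alignment()
        res = asap_delimit(aln, models=("p",), n_perm=99, seed=1,
                           reference_threshold=5e-4)
        best = res["p"][0]
        assert best.above_reference is (best.threshold_dist > 5e-4)


class TestEstimator:
    def test_fit_on_alignment_sets_labels(self):
        aln = _two_cluster_alignment()
        est = AsapPartitioner(models=("p", "K80"), n_perm=99, random_state=2)
        labels = est.fit_predict(aln)
        assert len(labels) == aln.n
        assert len(set(labels)) == est.best_.n_species == 2

    def test_fit_on_distance_matrix(self):
        est = AsapPartitioner(n_perm=99).fit(_dm_two_pairs())
        assert est.best_.n_species == 2

    def test_get_params_roundtrip(self):
        est = AsapPartitioner(n_perm=199)
        assert AsapPartitioner(**est.get_params()).n_perm == 199
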