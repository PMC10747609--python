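"""Alignment handling, haplotype collapsing and substitution-model distances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delimpy import (
    Alignment,
    build_population_dataset,
    collapse_haplotypes,
    pairwise_distances,
    read_alignment,
)
from delimpy.errors import AlignmentError, ParseError, SaturationError
from delimpy.seqdata import jc69_distance, k80_distance, pair_counts


class TestAlignment:
    def test_fasta_roundtrip_preserves_order_and_case(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">r2\nacgt\n>r1\nAC-N\n")
        aln = read_alignment(p)
        assert aln.ids == ["r2", "r1"]
        assert aln.seqs == ["ACGT", "AC-N"]
        assert aln.length == 4 and aln.n == 2
        out = tmp_path / "b.fasta"
        aln.write_fasta(out)
        again = read_alignment(out)
        assert again.ids == aln.ids and again.seqs == aln.seqs

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentError, match="length"):
            Alignment(["a", "b"], ["ACGTACGTAC", "ACGTACGTACG"])

    def test_illegal_character_names_record_and_column(self):
        with pytest.raises(ParseError, match=r"'X'.*'b'.*column 2"):
            Alignment(["a", "b"], ["ACGT", "ACXT"])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(AlignmentError, match="duplicate"):
            Alignment(["a", "a"], ["ACGT", "ACGT"])

    def test_empty_rejected(self):
        with pytest.raises(AlignmentError):
            Alignment([], [])


class TestCollapse:
    def test_equality_classes(self):
        aln = Alignment(
            ["r1", "r2", "r3", "r4", "r5"],
            ["AAAA", "CCCC", "AAAA", "CCCC", "GGGG"],
        )
        ht = collapse_haplotypes(aln)
        assert [h.count for h in ht.haplotypes] == [2, 2, 1]
        assert ht.haplotypes[0].members == ["r1", "r3"]
        # every record in exactly one haplotype
        members = [m for h in ht.haplotypes for m in h.members]
        assert sorted(members) == sorted(aln.ids)

    def test_n_wildcard_merges_only_under_policy(self):
        aln = Alignment(["a", "b"], ["ACGN", "ACGT"])
        assert collapse_haplotypes(aln, "strict").n == 2
        assert collapse_haplotypes(aln, "n_wildcard").n == 1

    def test_templates_recovered_by_brute_force(self):
        # 20 records from 4 templates; counts must match template multiplicity
        templates = ["AAAA", "CCCC", "GGGG", "TTTT"]
        rng = np.random.default_rng(7)
        picks = rng.integers(0, 4, size=20)
        aln = Alignment([f"r{i}" for i in range(20)],
                        [templates[k] for k in picks])
        ht = collapse_haplotypes(aln)
        assert ht.n == len(set(picks))
        # brute-force oracle: pairwise equality classes
        expected = sorted(np.bincount(picks, minlength=4), reverse=True)
        expected = [c for c in expected if c]
        assert [h.count for h in ht.haplotypes] == expected

    def test_population_membership_tracked(self):
        aln = Alignment(["r1", "r2", "r3"], ["AAAA", "AAAA", "CCCC"])
        ht = collapse_haplotypes(aln, populations={"r1": "p1", "r2": "p2", "r3": "p1"})
        assert ht.haplotypes[0].populations == {"p1": 1, "p2": 1}

    @given(st.lists(st.sampled_from(["AAAA", "AATA", "CCCC", "CGCC", "GGGG"]),
                    min_size=1, max_size=15))
    @settings(deadline=None, max_examples=50)
    def test_collapse_expand_inverse(self, seqs):
        """Collapsing then expanding with original counts restores the multiset."""
        aln = Alignment([f"r{i}" for i in range(len(seqs))], seqs)
        ht = collapse_haplotypes(aln)
        expanded = build_population_dataset(
            ht, {h.hap_id: h.count for h in ht.haplotypes}
        )
        assert sorted(expanded.seqs) == sorted(aln.seqs)


class TestPopulationDataset:
    def test_expansion(self):
        aln = Alignment(["r1", "r2", "r3", "r4"], ["AAAA"] * 3 + ["CCCC"])
        ht = collapse_haplotypes(aln)
        out = build_population_dataset(ht, {"h1": 3, "h2": 1})
        assert out.n == 4
        assert out.seqs.count("AAAA") == 3
        assert out.ids == ["h1_1", "h1_2", "h1_3", "h2_1"]

    def test_single_copies_roundtrip(self):
        aln = Alignment(["r1", "r2"], ["AAAA", "CCCC"])
        ht = collapse_haplotypes(aln)
        out = build_population_dataset(ht, {"h1": 1, "h2": 1})
        assert out.seqs == [h.sequence for h in ht.haplotypes]

    def test_unknown_id_rejected(self):
        ht = collapse_haplotypes(Alignment(["r1"], ["AAAA"]))
        with pytest.raises(KeyError):
            build_population_dataset(ht, {"nope": 1})


def _make_pair(L, n_ts, n_tv):
    """Two sequences of length L differing by n_ts transitions + n_tv transversions."""
    a = ["A"] * L
    b = ["A"] * L
    for i in range(n_ts):
        b[i] = "G"  # A->G transition
    for i in range(n_ts, n_ts + n_tv):
        b[i] = "C"  # A->C transversion
    return "".join(a), "".join(b)


class TestDistances:
    @pytest.mark.parametrize("model", ["p", "JC69", "K80"])
    def test_identical_sequences_zero(self, model):
        aln = Alignment(["a", "b"], ["ACGT" * 10] * 2)
        assert pairwise_distances(aln, model).D[0, 1] == 0.0

    def test_jc69_closed_form(self):
        # 100 sites, 15 differences
        assert jc69_distance(0.15) == pytest.approx(-0.75 * math.log(0.8), abs=1e-12)
        assert jc69_distance(0.15) == pytest.approx(0.167358, abs=1e-6)

    def test_k80_closed_form(self):
        # 100 sites, 10 transitions, 5 transversions
        expect = -0.5 * math.log(0.75) - 0.25 * math.log(0.90)
        assert k80_distance(0.10, 0.05) == pytest.approx(expect, abs=1e-12)
        assert k80_distance(0.10, 0.05) == pytest.approx(0.170181, abs=1e-6)

    def test_sequences_reproduce_closed_forms(self):
        a, b = _make_pair(100, 10, 5)
        aln = Alignment(["a", "b"], [a, b])
        assert pairwise_distances(aln, "p").D[0, 1] == pytest.approx(0.15)
        assert pairwise_distances(aln, "JC69").D[0, 1] == pytest.approx(
            0.167358, abs=1e-6
        )
        assert pairwise_distances(aln, "K80").D[0, 1] == pytest.approx(
            0.170181, abs=1e-6
        )

    def test_pairwise_deletion_drops_gap_and_n_columns(self):
        aln = Alignment(["a", "b"], ["ACGTN-GG", "TCGTAAGG"])
        enc = aln.encoded()
        pc = pair_counts(enc[0], enc[1])
        assert pc.L_eff == 6  # columns 4 (N) and 5 (-) dropped
        assert pc.diff == 1 and pc.transitions == 0 and pc.transversions == 1
        assert pc.p == pc.P + pc.Q

    def test_saturation_errors_name_the_pair(self):
        a, b = _make_pair(100, 0, 80)
        aln = Alignment(["s1", "s2"], [a, b])
        with pytest.raises(SaturationError, match="s1"):
            pairwise_distances(aln, "JC69")
        with pytest.raises(SaturationError, match="s1"):
            pairwise_distances(aln, "K80")

    def test_no_comparable_sites_rejected(self):
        aln = Alignment(["a", "b"], ["NNNN", "ACGT"])
        with pytest.raises(AlignmentError, match="comparable"):
            pairwise_distances(aln, "p")

    def test_jc69_dominates_p_distance(self):
        rng = np.random.default_rng(3)
        base = rng.choice(list("ACGT"), 200)
        seqs = []
        for _ in range(5):
            s = base.copy()
            hit = rng.random(200) < 0.15
            s[hit] = rng.choice(list("ACGT"), int(hit.sum()))
            seqs.append("".join(s))
        aln = Alignment([f"r{i}" for i in range(5)], seqs)
        P = pairwise_distances(aln, "p").D
        J = pairwise_distances(aln, "JC69").D
        iu = np.triu_indices(5, k=1)
        assert np.all(J[iu] >= P[iu])

    def test_k80_equals_jc69_at_one_to_two_ratio(self):
        # equal-rate expectation: transitions:transversions = 1:2
        for n_ts in (2, 6, 10):
            a, b = _make_pair(300, n_ts, 2 * n_ts)
            aln = Alignment(["a", "b"], [a, b])
            d_k = pairwise_distances(aln, "K80").D[0, 1]
            d_j = pairwise_distances(aln, "JC69").D[0, 1]
            assert d_k == pytest.approx(d_j, abs=1e-9)

    def test_record_permutation_permutes_matrix(self, toy_alignment):
        dm = pairwise_distances(toy_alignment, "K80")
        perm = [3, 0, 5, 1, 4, 2]
        aln2 = Alignment([toy_alignment.ids[i] for i in perm],
                         [toy_alignment.seqs[i] for i in perm])
        dm2 = pairwise_distances(aln2, "K80")
        P = np.ix_(perm, perm)
        assert np.allclose(dm.D[P], dm2.D)

    def test_site_counting_oracle(self, toy_alignment):
        """Distances on a 6-record toy match direct per-site counting."""
        dm = pairwise_distances(toy_alignment, "p")
        for i in range(6):
            for j in range(6):
                si, sj = toy_alignment.seqs[i], toy_alignment.seqs[j]
                diffs = sum(x != y for x, y in zip(si, sj))
                assert dm.D[i, j] == pytest.approx(diffs / len(si))

    def test_matrix_exports(self, toy_alignment, tmp_path):
        dm = pairwise_distances(toy_alignment, "p")
        dm.write_tsv(tmp_path / "d.tsv")
        dm.write_phylip(tmp_path / "d.phy")
        lines = (tmp_path / "d.tsv").read_text().splitlines()
        assert lines[0].split("\t")[1:] == dm.labels
        assert (tmp_path / "d.phy").read_text().splitlines()[0] == "6"
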