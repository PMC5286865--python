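"""Unit and property tests for the longest-match / ARSI scoring core."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arsi.core import (arsi_score, arsi_scores_leave_one_out, build_index,
                       longest_match_at, match_length_profile,
                       simulate_read_errors)

from conftest import brute_force_profile, random_instance

DNA = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestMatchLengths:
    def test_worked_example_profile(self):
        idx = build_index([("a", "ACGTA")])
        prof = match_length_profile(idx, "ACGTACGT")
        assert list(prof.lengths) == [5, 4, 3, 2, 4, 3, 2, 1]

    @pytest.mark.parametrize("i,expected", [(0, 5), (3, 2), (7, 1)])
    def test_longest_match_at(self, i, expected):
        idx = build_index([("a", "ACGTA")])
        assert longest_match_at(idx, "ACGTACGT", i) == expected

    def test_longest_match_out_of_range(self):
        idx = build_index([("a", "ACGTA")])
        with pytest.raises(IndexError):
            longest_match_at(idx, "ACGT", 4)

    def test_self_reference_is_maximal(self):
        idx = build_index([("a", "ACGTACGT")])
        assert list(match_length_profile(idx, "ACGTACGT").lengths) == \
            [8, 7, 6, 5, 4, 3, 2, 1]

    def test_disjoint_alphabet_scores_zero(self):
        idx = build_index([("c", "CCCC")])
        assert arsi_score(idx, "AAAA").value == 0.0

    def test_n_matches_nothing_in_query(self):
        idx = build_index([("a", "ACGTACGT")])
        assert list(match_length_profile(idx, "NNNN").lengths) == [0, 0, 0, 0]

    def test_n_matches_nothing_in_reference(self):
        idx = build_index([("a", "ACNGT")])
        # the N splits the reference: ACGT never matches across it
        assert longest_match_at(idx, "ACGT", 0) == 2

    def test_match_cannot_span_reference_boundary(self):
        idx = build_index([("a", "AAAC"), ("b", "GTTT")])
        assert longest_match_at(idx, "ACGT", 0) == 2  # "AC" from a only

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty reference"):
            build_index([])
        with pytest.raises(ValueError, match="empty reference"):
            build_index([("a", "")])

    def test_order_and_duplicate_invariance(self):
        refs = [("a", "ACGTAGGA"), ("b", "TTACGG"), ("c", "GGGAAC")]
        q = "ACGTACGGGAAT"
        base = list(match_length_profile(build_index(refs), q).lengths)
        shuffled = list(match_length_profile(build_index(refs[::-1]), q).lengths)
        doubled = list(match_length_profile(
            build_index(refs + [("d", "ACGTAGGA")]), q).lengths)
        assert base == shuffled == doubled


class TestArsiScore:
    def test_worked_example(self):
        idx = build_index([("a", "ACGTA")])
        assert arsi_score(idx, "ACGTACGT").value == pytest.approx(3.0)

    @pytest.mark.parametrize("n", [1, 2, 7, 16, 33])
    def test_self_reference_closed_form(self, n):
        rnd = random.Random(n)
        s = "".join(rnd.choice("ACGT") for _ in range(n))
        idx = build_index([("self", s)])
        # maximal profile n, n-1, ..., 1 gives mean (n+1)/2
        assert arsi_score(idx, s).value == pytest.approx((n + 1) / 2)


class TestPropertyVsOracle:
    def test_random_instances_match_brute_force(self):
        rnd = random.Random(123)
        for _ in range(200):
            S, refs = random_instance(rnd)
            idx = build_index([(f"r{i}", r) for i, r in enumerate(refs)])
            assert list(match_length_profile(idx, S).lengths) == \
                brute_force_profile(S, refs)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(s=DNA, refs=st.lists(DNA, min_size=1, max_size=4),
           extra=DNA)
    def test_structural_invariants_and_monotonicity(self, s, refs, extra):
        """L(i) <= |S|-i, the shift bound, and reference monotonicity."""
        idx = build_index([(f"r{i}", r) for i, r in enumerate(refs)])
        L = match_length_profile(idx, s).lengths
        n = len(s)
        assert all(0 <= L[i] <= n - i for i in range(n))
        assert all(L[i + 1] >= L[i] - 1 for i in range(n - 1))
        bigger = build_index(
            [(f"r{i}", r) for i, r in enumerate(refs)] + [("x", extra)])
        L2 = match_length_profile(bigger, s).lengths
        assert np.all(L2 >= L)


class TestLeaveOneOut:
    def test_reduces_to_plain_score(self):
        scores = arsi_scores_leave_one_out(
            [("a", "g1", "ACGTA"), ("b", "g2", "ACGTACGT")])
        by_id = {s.element_id: s.value for s in scores}
        assert by_id["b"] == pytest.approx(3.0)

    def test_identical_elements_in_different_genes(self):
        scores = arsi_scores_leave_one_out(
            [("a", "g1", "ACGTACGT"), ("b", "g2", "ACGTACGT")])
        assert all(s.value == pytest.approx(4.5) for s in scores)

    def test_gene_exclusion_blocks_same_gene_matches(self):
        # both elements of g1 share sequence; g2 is disjoint in 2-mers
        scores = arsi_scores_leave_one_out(
            [("a", "g1", "ACGTACGT"), ("b", "g1", "ACGTACGT"),
             ("c", "g2", "TTTTTTTT")])
        by_id = {s.element_id: s.value for s in scores}
        assert by_id["a"] < 4.5  # cannot match its gene-mate
        strict = arsi_scores_leave_one_out(
            [("a", "g1", "ACGTACGT"), ("b", "g1", "ACGTACGT"),
             ("c", "g2", "TTTTTTTT")], exclusion="element")
        by_id_strict = {s.element_id: s.value for s in strict}
        assert by_id_strict["a"] == pytest.approx(4.5)

    def test_loo_matches_brute_force_with_grouping(self):
        rnd = random.Random(7)
        for _ in range(50):
            els = [(f"e{i}", f"g{i // 2}",
                    "".join(rnd.choice("ACGT") for _ in range(rnd.randint(5, 60))))
                   for i in range(rnd.randint(2, 8))]
            for s in arsi_scores_leave_one_out(els):
                refs = [seq for eid, gid, seq in els if gid != s.gene_id]
                exp = sum(brute_force_profile(
                    next(q for e, g, q in els if e == s.element_id), refs)) / s.length
                assert s.value == pytest.approx(exp)

    def test_single_element_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            arsi_scores_leave_one_out([("a", "g1", "ACGT")])

    def test_both_strands_flag(self):
        els = [("a", "g1", "AACCGGTT"), ("b", "g2", "AACCGGTT")]
        fwd = arsi_scores_leave_one_out(els)[0].value
        both = arsi_scores_leave_one_out(els, both_strands=True)[0].value
        assert both >= fwd


class TestReadErrors:
    def test_zero_rate_is_identity(self):
        seqs = ["ACGTACGT", "TTTT"]
        assert simulate_read_errors(seqs, 0.0, seed=1) == seqs

    def test_rate_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_read_errors(["ACGT"], 1.0)

    def test_seed_determinism_and_binomial_rate(self):
        seq = "ACGT" * 25000  # 1e5 nt
        a = simulate_read_errors([seq], 1e-2, seed=42)[0]
        b = simulate_read_errors([seq], 1e-2, seed=42)[0]
        assert a == b
        n_mut = sum(x != y for x, y in zip(a, seq))
        # Binomial(1e5, 1e-2): mean 1000, sd ~31; allow 6 sd
        assert 800 < n_mut < 1200
        assert len(a) == len(seq)

    def test_n_positions_untouched(self):
        assert simulate_read_errors(["NNNN"], 0.5, seed=0) == ["NNNN"]
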