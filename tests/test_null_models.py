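"""Randomization schemes: conservation laws, commutation, Z-scoring."""

import numpy as np
import pytest
from Bio.Seq import Seq

from arsi.null_models import (ConsensusSpec, cyclic_shift_utr,
                              paired_real_vs_random_test, permute_intron,
                              permute_synonymous_codons, randomize_genome,
                              randomize_parts, zscore_profile, zscore_scalars)
from arsi.profiles import AlignedAnchorProfile, WindowParams
from arsi.sequence_io import GeneParts
from arsi.null_models import NullEnsemble


def _translate(orf):
    return str(Seq(orf).translate())


class TestCodonPermutation:
    def test_singleton_families_are_identity(self):
        out = permute_synonymous_codons([("g1", "ATGTTATAA")], seed=0)
        assert out == [("g1", "ATGTTATAA")]

    def test_two_gene_multiset_conservation(self):
        # Leu codons CTT and TTA appear once each; they may swap but both survive
        orfs = [("g1", "ATGCTTTAA"), ("g2", "ATGTTATAG")]
        seen = set()
        for seed in range(10):
            out = dict(permute_synonymous_codons(orfs, seed=seed))
            leu = {out["g1"][3:6], out["g2"][3:6]}
            assert leu == {"CTT", "TTA"}
            seen.add((out["g1"], out["g2"]))
        assert len(seen) > 1  # the permutation actually permutes

    def test_proteome_and_codon_counts_conserved(self, small_parts):
        orfs = [(p.gene_id, p.orf) for p in small_parts]
        out = permute_synonymous_codons(orfs, seed=3)
        def counts(pairs):
            c = {}
            for _, s in pairs:
                for i in range(0, len(s), 3):
                    c[s[i:i + 3]] = c.get(s[i:i + 3], 0) + 1
            return c
        assert counts(orfs) == counts(out)
        for (gid, a), (_, b) in zip(orfs, out):
            assert _translate(a) == _translate(b), gid

    def test_non_triplet_orf_left_unchanged(self, caplog):
        out = permute_synonymous_codons([("g1", "ATGC"), ("g2", "ATGAAATAA")],
                                        seed=1)
        assert out[0] == ("g1", "ATGC")


class TestIntronPermutation:
    INTRON = "GTATGT" + "ACCAGGTTCCAA" + "TACTAAC" + "GCTT" + "CAG"

    def test_consensus_positions_fixed_and_composition_conserved(self):
        spec = ConsensusSpec()
        for seed in range(5):
            out = permute_intron(self.INTRON, spec, seed=seed)
            assert out[:6] == "GTATGT"
            assert out[-3:] == "CAG"
            bs = self.INTRON.index("TACTAAC")
            assert out[bs:bs + 7] == "TACTAAC"
            assert sorted(out) == sorted(self.INTRON)

    def test_uniform_free_positions_are_identity(self):
        intron = "GTATGT" + "AAAA" + "TACTAAC" + "AAAA" + "AAG"
        assert permute_intron(intron, seed=0) == intron

    def test_too_short_intron_unchanged(self):
        assert permute_intron("GTATGTAG", seed=0) == "GTATGTAG"

    def test_no_branch_motif_still_fixes_termini(self):
        intron = "GTATGT" + "C" * 30 + "AAG"
        out = permute_intron(intron, seed=1)
        assert out[:6] == "GTATGT" and out[-3:] == "AAG"
        assert sorted(out) == sorted(intron)


class TestUtrRotation:
    def test_rotation_definition(self):
        # rotating "ACGTAC" right by 2 gives "ACACGT"
        out = cyclic_shift_utr("ACGTAC", "three", rng=_FixedRot(2))
        assert out == "ACACGT"

    def test_five_prime_context_fixed(self):
        utr = "AAAACCCGGG"
        for seed in range(5):
            out = cyclic_shift_utr(utr, "five", context_len=6, seed=seed)
            assert out[-6:] == utr[-6:]
            assert sorted(out) == sorted(utr)

    def test_composition_and_length_conserved(self):
        utr = "ACGTACGTTTGCA"
        for seed in range(5):
            out = cyclic_shift_utr(utr, "three", seed=seed)
            assert len(out) == len(utr) and sorted(out) == sorted(utr)

    def test_tiny_utr_unchanged(self):
        assert cyclic_shift_utr("A", "three", seed=0) == "A"
        assert cyclic_shift_utr("ACGT", "five", context_len=6, seed=0) == "ACGT"


class _FixedRot:
    """Stand-in RNG returning a fixed rotation offset."""

    def __init__(self, r):
        self.r = r

    def integers(self, lo, hi):
        return self.r


class TestSchemeIsolationAndCommutation:
    def test_codons_only_leaves_introns_and_utrs_identical(self, small_parts):
        out = randomize_parts(small_parts, ("codons",), seed=5)
        for p, q in zip(small_parts, out):
            assert p.five_utr == q.five_utr and p.three_utr == q.three_utr
            assert p.introns == q.introns

    def test_same_seed_same_ensemble(self, small_parts):
        a = randomize_parts(small_parts, ("codons", "introns", "utrs"), seed=9)
        b = randomize_parts(small_parts, ("codons", "introns", "utrs"), seed=9)
        assert all(pa.premrna() == pb.premrna() for pa, pb in zip(a, b))

    @pytest.mark.parametrize("order", [("codons", "introns", "utrs"),
                                       ("utrs", "codons", "introns"),
                                       ("introns", "utrs", "codons")])
    def test_schemes_commute(self, small_parts, order):
        combined = randomize_parts(small_parts, ("codons", "introns", "utrs"),
                                   seed=21)
        seq = list(small_parts)
        for s in order:
            seq = randomize_parts(seq, (s,), seed=21)
        assert all(a.premrna() == b.premrna() for a, b in zip(combined, seq))

    def test_unknown_scheme_rejected(self, small_parts):
        with pytest.raises(ValueError, match="unknown scheme"):
            randomize_parts(small_parts, ("exons",), seed=0)


class TestEnsembleAndZ:
    def test_r_below_two_rejected(self, small_parts):
        with pytest.raises(ValueError, match="R must be >= 2"):
            randomize_genome(small_parts, ("codons",), R=1, seed=0,
                             score_kind="orf")

    def test_replicate_scores_shape_and_determinism(self, small_parts):
        ens1 = randomize_genome(small_parts[:20], ("codons",), R=3, seed=4,
                                score_kind="orf")
        ens2 = randomize_genome(small_parts[:20], ("codons",), R=3, seed=4,
                                score_kind="orf")
        assert ens1.scores.shape == (3, 20)
        assert np.array_equal(ens1.scores, ens2.scores)

    def test_zscore_scalars_trivia(self):
        null = np.array([[1.0, 5.0], [3.0, 5.0], [2.0, 5.0]])
        real = np.array([2.0, 7.0])
        z, mu, sd = zscore_scalars(real, null)
        assert z[0] == pytest.approx(0.0)      # real equals null mean
        assert np.isnan(z[1])                  # sd = 0 flagged, not inf
        real2 = mu + 2 * sd
        z2, _, _ = zscore_scalars(real2, null)
        assert z2[0] == pytest.approx(2.0)

    def test_zscore_profile_flags_undefined_offsets(self):
        offsets = np.arange(-2, 3)
        real = AlignedAnchorProfile("orf_start", offsets,
                                    np.array([1., 2., 3., 4., np.nan]),
                                    np.array([2, 2, 2, 2, 0]))
        null = np.array([[1., 1., 3., 4., np.nan],
                         [3., 1., 3., 2., np.nan]])
        ens = NullEnsemble(("codons",), 2, 0, offsets=offsets,
                           anchor_profiles={"orf_start": null})
        zp = zscore_profile(real, ens)
        assert zp.z[0] == pytest.approx(-1 / np.sqrt(2))  # (1-2)/sd(1,3)
        assert not zp.defined[1]               # sd 0
        assert not zp.defined[4]               # no data
        assert np.isnan(zp.z[4])


class TestPairedTest:
    def test_identical_vectors_give_p_one(self):
        res = paired_real_vs_random_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0 and "zero" in res.note

    def test_uniform_shift_is_highly_significant(self):
        rnd = np.random.default_rng(0)
        rand = rnd.normal(size=50)
        real = rand + 1.0
        res = paired_real_vs_random_test(real, rand)
        assert res.p_value < 1e-8
        assert res.median_real - res.median_random == pytest.approx(1.0)

    def test_antisymmetric_differences_not_significant(self):
        rand = np.arange(20, dtype=float)
        diffs = np.concatenate([np.arange(1, 11), -np.arange(1, 11)])
        res = paired_real_vs_random_test(rand + diffs, rand)
        assert res.p_value > 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_real_vs_random_test([1.0], [1.0, 2.0])
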