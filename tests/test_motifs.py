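import itertools
import math

import numpy as np
import pytest

from regulonkit._seq import iupac_revcomp
from regulonkit.motifs import (DiscoveryError, MotifGeometry, build_pwm,
                               consensus, discover_direct_repeat,
                               discover_palindrome_em, is_palindromic,
                               score_word)
from conftest import random_dna


class TestGeometry:
    @pytest.mark.parametrize("b,s", [(16, 5), (12, 9), (14, 6), (10, 3)])
    def test_center_distance_is_box_plus_spacer(self, b, s):
        g = MotifGeometry("direct_repeat", b, s)
        assert g.center_distance == b + s
        assert g.total_len == 2 * b + s
        assert g.scoring_length == 2 * b

    def test_susr_style_center_distances(self):
        # 67/77 bp center spacing with a 12-bp box
        for center in (67, 77):
            g = MotifGeometry("direct_repeat", 12, center - 12)
            assert g.center_distance == center

    def test_direct_repeat_requires_box_and_spacer(self):
        with pytest.raises(ValueError):
            MotifGeometry("direct_repeat", box_len=16)


class TestBuildPwm:
    def test_hand_computed_two_site_matrix(self):
        # sites {AC, AG}, uniform background, pseudocount 0.5:
        # f = (count + 0.5*0.25) / 2.5 -> 0.85 / 0.45 / 0.05
        m = build_pwm(["AC", "AG"], pseudocount=0.5)
        f = m.freqs
        expected = {
            (0, 0): 0.85,  # A in column 0
            (1, 1): 0.45, (2, 1): 0.45,  # C and G in column 1
            (3, 0): 0.05, (0, 1): 0.05,
        }
        for (b, j), v in expected.items():
            assert f[b, j] == pytest.approx(v)
        assert m.pwm[0, 0] == pytest.approx(math.log2(0.85 / 0.25))
        assert m.pwm[1, 1] == pytest.approx(math.log2(0.45 / 0.25))

    def test_identical_sites_ic_limit_two_bits(self):
        m = build_pwm(["ACGT"] * 10, pseudocount=1e-9)
        assert m.information_content == pytest.approx([2, 2, 2, 2], abs=1e-6)
        assert m.total_information == pytest.approx(8.0, abs=1e-5)

    def test_background_matching_column_zero_ic(self):
        m = build_pwm(["AA", "CA", "GA", "TA"], pseudocount=1e-9)
        assert m.information_content[0] == pytest.approx(0.0, abs=1e-6)
        assert m.information_content[1] == pytest.approx(2.0, abs=1e-6)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACG", "AC"])

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["AC"], background=[0.5, 0.5, 0.0, 0.0])

    def test_counts_sum_to_n_sites(self):
        m = build_pwm(["ACGT", "AGGT", "ACGA"])
        assert (m.counts.sum(axis=0) == 3).all()


class TestScoreWord:
    def test_consensus_word_is_argmax(self):
        m = build_pwm(["ACGT", "ACGT", "ACGA"])
        best = max(("".join(w) for w in itertools.product("ACGT", repeat=4)),
                   key=lambda w: score_word(m, w))
        cols = m.freqs.argmax(axis=0)
        assert best == "".join("ACGT"[c] for c in cols)

    def test_ranking_matches_exhaustive_enumeration(self, rng):
        sites = ["".join(random_dna(rng, 4)) for _ in range(6)]
        m = build_pwm(sites, pseudocount=0.5)
        f, bg = m.freqs, m.background

        def oracle(w):
            return sum(math.log2(f["ACGT".index(c), j] / bg["ACGT".index(c)])
                       for j, c in enumerate(w))

        words = ["".join(w) for w in itertools.product("ACGT", repeat=4)]
        impl = sorted(words, key=lambda w: (score_word(m, w), w))
        ref = sorted(words, key=lambda w: (oracle(w), w))
        assert impl == ref
        for w in words[:16]:
            assert score_word(m, w) == pytest.approx(oracle(w))

    def test_ambiguous_word_scores_neg_inf(self):
        m = build_pwm(["ACGT"])
        assert score_word(m, "ACNT") == float("-inf")

    def test_length_mismatch_rejected(self):
        m = build_pwm(["ACGT"])
        with pytest.raises(ValueError):
            score_word(m, "ACG")

    def test_huge_pseudocount_prior_dominated(self):
        m = build_pwm(["ACGT"], pseudocount=1e9)
        assert abs(score_word(m, "TTTT")) < 1e-6


class TestDirectRepeatDiscovery:
    def plant(self, rng, n, box_len, spacer, noise=0.0, length=250):
        box = random_dna(rng, box_len)
        seqs = []
        for _ in range(n):
            word = "".join(
                c if rng.random() >= noise else "ACGT"[rng.integers(4)]
                for c in box + box)
            site = word[:box_len] + random_dna(rng, spacer) + word[box_len:]
            pos = int(rng.integers(0, length - len(site)))
            bg = random_dna(rng, length)
            seqs.append(bg[:pos] + site + bg[pos + len(site):])
        return seqs

    def test_recovers_exact_planted_geometry(self, rng):
        seqs = self.plant(rng, 10, 16, 5)
        m = discover_direct_repeat(seqs, seed=0)
        assert (m.geometry.box_len, m.geometry.spacer) == (16, 5)
        assert m.geometry.center_distance == 21

    def test_recovers_12_9_under_noise(self, rng):
        seqs = self.plant(rng, 10, 12, 9, noise=0.10)
        m = discover_direct_repeat(seqs, seed=0)
        assert m.geometry.center_distance == 21
        assert (m.geometry.box_len, m.geometry.spacer) == (12, 9)

    def test_background_ic_below_planted_ic(self, rng):
        planted = discover_direct_repeat(self.plant(rng, 10, 16, 5), seed=0)
        null_seqs = [random_dna(rng, 250) for _ in range(10)]
        null = discover_direct_repeat(null_seqs, seed=0)
        assert null.total_information < planted.total_information

    def test_all_ambiguous_input_fails(self):
        with pytest.raises(DiscoveryError):
            discover_direct_repeat(["N" * 100] * 5)

    def test_deterministic_given_seed(self, rng):
        seqs = self.plant(rng, 8, 12, 5)
        m1 = discover_direct_repeat(seqs, seed=3)
        m2 = discover_direct_repeat(seqs, seed=3)
        assert np.array_equal(m1.counts, m2.counts)
        assert m1.training_sites == m2.training_sites


class TestPalindromeEM:
    CRP = "wwwTATGTTnTAnAACATAwww"

    def sample_pal(self, rng, cons):
        out = []
        for ch in cons.upper():
            if ch == "W":
                out.append("AT"[rng.integers(2)])
            elif ch == "N":
                out.append("ACGT"[rng.integers(4)])
            else:
                out.append(ch)
        return "".join(out)

    def test_fixed_palindrome_converges_immediately(self):
        pal = "TATGTTATAACATA"  # even-length palindrome
        assert pal == iupac_revcomp(pal)
        m = discover_palindrome_em([pal] * 4, motif_len=len(pal),
                                   n_restarts=2, seed=0)
        assert consensus(m) == pal

    def test_frequency_matrix_exactly_symmetric(self, rng):
        seqs = [random_dna(rng, 60) for _ in range(5)]
        m = discover_palindrome_em(seqs, motif_len=10, n_restarts=3, seed=1)
        f = m.freqs
        assert np.array_equal(f, f[::-1, ::-1])

    def test_planted_crp_consensus_recovered(self, rng):
        seqs = []
        for _ in range(12):
            site = self.sample_pal(rng, self.CRP)
            bg = random_dna(rng, 120)
            pos = int(rng.integers(0, 120 - 22))
            seqs.append(bg[:pos] + site + bg[pos + 22:])
        m = discover_palindrome_em(seqs, motif_len=22, n_restarts=10, seed=0)
        got = consensus(m)
        assert is_palindromic(got)
        for g, p in zip(got, self.CRP):
            if p.isupper():
                assert g == p

    def test_motif_longer_than_sequences_rejected(self):
        with pytest.raises(ValueError):
            discover_palindrome_em(["ACGT"] * 5, motif_len=10)


class TestConsensus:
    def test_column_rules(self):
        m = build_pwm(["AAAC", "AACG", "ATGT"], pseudocount=1e-9)
        c = consensus(m, strong=0.7, weak_pair=0.8)
        assert c[0] == "A"        # 3/3 A
        assert c[1] in "wm"       # A 2/3 + one other
        assert c[3] == "n"        # C, G, T: no pair >= 0.8

    def test_half_half_is_w(self):
        m = build_pwm(["AT", "TA"], pseudocount=1e-9)
        assert consensus(m) == "ww"

    def test_direct_repeat_consensus_has_spacer_ns(self):
        geom = MotifGeometry("direct_repeat", 3, 2)
        m = build_pwm(["ACGACG"], geometry=geom, pseudocount=1e-9)
        assert consensus(m) == "ACGnnACG"


class TestIsPalindromic:
    @pytest.mark.parametrize("s,expected", [
        ("wwwTATGTTnTAnAACATAwww", True),
        ("ACGT", True),
        ("AAC", False),
        ("wsw", True),
        ("RY", True),
        ("RR", False),
    ])
    def test_cases(self, s, expected):
        assert is_palindromic(s) is expected

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError):
            is_palindromic("ACXT")

    def test_case_normalization_lossless(self):
        s = "wwwTATGTTnTAnAACATAwww"
        assert is_palindromic(s) == is_palindromic(s.upper()) \
            == is_palindromic(s.lower())


class TestWriters:
    def test_meme_and_transfac_emit_parseable_text(self, rng):
        from regulonkit.motifs import to_meme, to_transfac, text_logo
        m = build_pwm([random_dna(rng, 8) for _ in range(4)])
        meme = to_meme({"m1": m})
        assert "MOTIF m1" in meme and "w= 8" in meme
        tf = to_transfac("m1", m)
        assert tf.startswith("ID m1") and tf.rstrip().endswith("//")
        logo = text_logo(m)
        assert len(logo.strip().split("\n")) == 8


class TestExtendedCenterMode:
    def test_susr_style_long_center_distance_recovered(self, rng):
        # two 12-bp boxes 67 bp center-to-center, as SusR-type dimers bind
        box = random_dna(rng, 12)
        seqs = []
        for _ in range(8):
            site = box + random_dna(rng, 55) + box
            bg = random_dna(rng, 320)
            pos = int(rng.integers(0, 320 - len(site)))
            seqs.append(bg[:pos] + site + bg[pos + len(site):])
        m = discover_direct_repeat(seqs, box_len_range=(10, 14),
                                   spacer_range=(3, 6), seed=0,
                                   extended_centers=range(60, 81))
        assert m.geometry.center_distance == 67
        assert m.geometry.box_len == 12
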