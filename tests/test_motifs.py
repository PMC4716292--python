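import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ck2phospho import motifs


class TestExtractWindow:
    def test_left_pad_forced_by_arithmetic(self):
        proteome = {"P": "MKKKSDEEDAAAAAA"}
        assert motifs.extract_window(proteome, "P", 5) == "XXXMKKKSDEEDAAA"

    def test_full_left_pad_at_n_terminus(self):
        assert motifs.extract_window({"P": "SAAAAAAAA"}, "P", 1) == "XXXXXXXSAAAAAAA"

    def test_right_pad_at_c_terminus(self):
        seq = "A" * 10 + "S"
        w = motifs.extract_window({"P": seq}, "P", 11)
        assert w == "AAAAAAAS" + "X" * 7

    def test_center_must_be_phosphorylatable(self):
        with pytest.raises(motifs.WindowError):
            motifs.extract_window({"P": "AAAAAAAAA"}, "P", 5)
        with pytest.raises(motifs.WindowError):
            motifs.extract_window({}, "Q", 1)

    @given(site=st.integers(1, 60), length=st.integers(1, 60))
    @settings(max_examples=200, deadline=None)
    def test_window_length_and_pad_count(self, site, length):
        if site > length:
            return
        seq = "S" * length
        w = motifs.extract_window({"P": seq}, "P", site)
        assert len(w) == 15
        expected_x = max(0, 8 - site) + max(0, site + 7 - length)
        assert w.count("X") == expected_x


class TestCk2Match:
    @pytest.mark.parametrize(
        "window, matched",
        [
            ("XXXXXXXSDXXXXXX", True),  # S/T-D/E
            ("XXXXXXXSADXXXXX", True),  # S/T-X-D/E
            ("XXXXXXXSAAEXXXX", True),  # S/T-X-X-D/E
            ("XXXXXXXTEEEXXXX", True),  # S/T-D/E-D/E-D/E
            ("XXXXXXXYDXXXXXX", False),  # centre Y outside the S/T consensus
            ("XXXXXXXSAAAXXXX", False),  # no acidic residue downstream
            ("XXXXXXXSXXXXXXX", False),  # padding never counts as acidic
            ("DDDDDDDSAAAAAAA", False),  # upstream acidics are irrelevant
        ],
    )
    def test_pattern_union(self, window, matched):
        assert motifs.ck2_match(window)[0] is matched

    def test_matched_patterns_reported_individually(self):
        _, names = motifs.ck2_match("XXXXXXXSEEEXXXX")
        assert "S/T-D/E" in names and "S/T-D/E-D/E-D/E" in names

    @given(st.text(alphabet=motifs.AMINO_ACIDS, min_size=11, max_size=11))
    @settings(max_examples=200, deadline=None)
    def test_invariant_to_offsets_outside_plus1_to_plus3(self, other):
        # vary everything except the centre and +1..+3
        core = "TED"  # +1..+3
        w1 = other[:7] + "S" + core + other[7:] + "X"
        w2 = "A" * 7 + "S" + core + "GGGG"
        assert motifs.ck2_match(w1[:15])[0] == motifs.ck2_match(w2)[0]

    def test_percentage_counts_motifs_with_any_matching_site(self):
        groups = [
            ["XXXXXXXSDXXXXXX"],
            ["XXXXXXXSAAAXXXX", "XXXXXXXSAAAXXXX"],
            ["XXXXXXXSAAAXXXX"],
            ["XXXXXXXYAAAXXXX"],
        ]
        assert motifs.ck2_percentage(groups) == 25.0

    def test_percentage_of_empty_group_is_flagged(self):
        with pytest.raises(ValueError):
            motifs.ck2_percentage([])


class TestBackground:
    def test_enumeration_of_tiny_proteome(self):
        p = motifs.background_frequencies({"P1": "ASA"})
        a = motifs.AA_INDEX["A"]
        jm1 = motifs.OFFSETS.index(-1)
        jp1 = motifs.OFFSETS.index(1)
        assert p[a, jm1] == 1.0 and p[a, jp1] == 1.0
        # all other offsets fall off the protein: zero effective count
        used = {jm1, jp1}
        for j in range(len(motifs.OFFSETS)):
            if j not in used:
                assert p[:, j].sum() == 0.0

    def test_probabilities_sum_to_one_per_used_position(self, small_dataset):
        p = motifs.background_frequencies(small_dataset["proteome"])
        sums = p.sum(axis=0)
        assert np.allclose(sums[sums > 0], 1.0)

    def test_uniform_proteome_near_one_twentieth(self):
        rng = np.random.default_rng(12)
        proteome = {
            f"U{i}": "".join(rng.choice(list(motifs.AMINO_ACIDS), 400)) for i in range(30)
        }
        p = motifs.background_frequencies(proteome)
        counts = p.sum(axis=0)  # just to locate used columns
        n_centers = sum(
            sum(1 for c in s if c in "STY") for s in proteome.values()
        )
        se = 3 * math.sqrt((1 / 20) * (19 / 20) / n_centers)
        mid = len(motifs.OFFSETS) // 2  # central offsets: almost no padding
        assert abs(p[:, mid] - 0.05).max() < 5 * se  # column-wise, generous
        assert counts[mid] == pytest.approx(1.0)

    def test_no_sty_proteome_rejected(self):
        with pytest.raises(ValueError):
            motifs.background_frequencies({"P": "AAAA"})


def _brute_force_tail(k, n, p, upper):
    rng = range(k, n + 1) if upper else range(0, k + 1)
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in rng)


class TestBinomialLogOdds:
    def test_closed_form_underrepresentation(self):
        # k=0, n=10, p=0.05: P(X<=0) = 0.95^10
        score = motifs.binomial_tail_log10(0, 10, 0.05)
        assert score == pytest.approx(10 * math.log10(0.95), abs=1e-12)
        assert score < 0

    def test_exact_tail_against_enumeration(self):
        score = motifs.binomial_tail_log10(6, 10, 0.05)
        assert score == pytest.approx(-math.log10(_brute_force_tail(6, 10, 0.05, True)), abs=1e-10)

    def test_brute_force_agreement_to_1e10_for_n_up_to_50(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(1, 51))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.01, 0.99))
            got = motifs.binomial_tail_log10(k, n, p)
            if k / n > p:
                expected = -math.log10(_brute_force_tail(k, n, p, True))
            elif k / n < p:
                expected = math.log10(_brute_force_tail(k, n, p, False))
            else:
                expected = 0.0
            assert got == pytest.approx(expected, abs=1e-10)

    def test_impossible_under_background_is_inf(self):
        assert motifs.binomial_tail_log10(1, 10, 0.0) == math.inf


class TestPlogo:
    def test_counts_partition_per_position(self, small_dataset):
        proteome = small_dataset["proteome"]
        bg = motifs.background_frequencies(proteome)
        windows = []
        for acc in list(proteome)[:20]:
            seq = proteome[acc]
            for i, c in enumerate(seq):
                if c in "STY":
                    windows.append(motifs.extract_window(proteome, acc, i + 1))
        logo = motifs.plogo_scores(windows[:300], bg)
        assert (logo.k.sum(axis=0) == logo.n).all()

    def test_planted_overrepresentation_is_significant_and_positive(self):
        rng = np.random.default_rng(31)
        proteome = {
            f"U{i}": "".join(rng.choice(list(motifs.AMINO_ACIDS), 500)) for i in range(40)
        }
        bg = motifs.background_frequencies(proteome)
        # all-acidic +1: D enrichment at +1 must dominate
        windows = ["AAAAAAASDAAAAAA"] * 100
        logo = motifs.plogo_scores(windows, bg)
        jp1 = motifs.OFFSETS.index(1)
        d = motifs.AA_INDEX["D"]
        assert logo.score[d, jp1] > logo.sig_threshold
        assert logo.significant[d, jp1]

    def test_null_draws_rarely_cross_bonferroni(self):
        rng = np.random.default_rng(41)
        proteome = {
            f"U{i}": "".join(rng.choice(list(motifs.AMINO_ACIDS), 400)) for i in range(40)
        }
        bg = motifs.background_frequencies(proteome)
        centers = [
            (acc, i + 1)
            for acc, seq in proteome.items()
            for i, c in enumerate(seq)
            if c in "STY"
        ]
        # the Bonferroni line guarantees <=5% family-wise error per direction
        # (280 one-tailed tests at alpha/280 each way)
        exceed_over = exceed_under = 0
        n_rep = 100
        for _ in range(n_rep):
            idx = rng.integers(0, len(centers), 200)
            windows = [motifs.extract_window(proteome, *centers[i]) for i in idx]
            logo = motifs.plogo_scores(windows, bg)
            finite = np.isfinite(logo.score)
            exceed_over += bool((logo.score[finite] > logo.sig_threshold).any())
            exceed_under += bool((logo.score[finite] < -logo.sig_threshold).any())
        assert exceed_over <= 5
        assert exceed_under <= 5

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(51)
        proteome = {"U": "".join(rng.choice(list(motifs.AMINO_ACIDS), 2000))}
        bg = motifs.background_frequencies(proteome)
        windows = ["AAAAAAASDAAAAAA", "CCCCCCCTEECCCCC"]
        logo = motifs.plogo_scores(windows, bg)
        d = logo.to_dict()
        back = motifs.LogoMatrix.from_dict(d)
        finite = np.isfinite(logo.score)
        assert np.allclose(back.score[finite], logo.score[finite])
        assert (back.k == logo.k).all() and (back.n == logo.n).all()
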