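"""PWM scoring, exact null distributions, shuffles and threshold calibration."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats


from regulonkit.motifscan import (
    PWM,
    best_hit_pvalue,
    best_hit_pvalues,
    build_pwm,
    calibrate_threshold,
    read_meme,
    read_presence,
    scan_regions,
    score_distribution,
    score_window,
    shuffle_sequence,
    write_meme,
    write_presence,
)
from conftest import random_seq


class TestBuildPwm:
    def test_single_site_zero_pseudocount_gives_unit_rows(self):
        pwm = build_pwm(["ACGT"], pseudocount=0.0)
        assert np.allclose(pwm.probs, np.eye(4))

    def test_pseudocount_arithmetic(self):
        pwm = build_pwm(["AA", "AA"], pseudocount=0.25)
        assert np.allclose(pwm.probs[:, 0], 2.25 / 3.0)
        assert np.allclose(pwm.probs[:, 1:], 0.25 / 3.0)

    def test_rows_always_normalized(self):
        rng = np.random.default_rng(1)
        sites = [random_seq(rng, 7) for _ in range(9)]
        pwm = build_pwm(sites)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)

    def test_non_acgt_site_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            build_pwm(["ACNT"])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            build_pwm(["ACG", "ACGT"])


class TestScoreWindow:
    def test_uniform_pwm_scores_zero(self):
        pwm = PWM("flat", np.full((6, 4), 0.25))
        assert score_window(pwm, "ACGTAC") == pytest.approx(0.0)

    def test_consensus_attains_maximum(self, panel):
        for pwm in panel.values():
            assert score_window(pwm, pwm.consensus) == pytest.approx(pwm.max_score())

    def test_matches_direct_hand_sum(self, panel):
        rng = np.random.default_rng(2)
        pwm = panel["E2F"]
        for _ in range(10):
            win = random_seq(rng, pwm.width)
            expected = sum(
                math.log2(pwm.probs[i, "ACGT".index(b)] / pwm.background["ACGT".index(b)])
                for i, b in enumerate(win)
            )
            assert score_window(pwm, win) == pytest.approx(expected, abs=1e-12)

    def test_minus_strand_scores_reverse_complement(self, panel):
        pwm = panel["RAM"]
        rng = np.random.default_rng(3)
        win = random_seq(rng, pwm.width)
        rc = win.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert score_window(pwm, win, strand="-") == pytest.approx(score_window(pwm, rc))

    def test_length_mismatch_raises(self, panel):
        with pytest.raises(ValueError, match="length"):
            score_window(panel["E2F"], "ACGT")

    def test_window_with_n_is_unscorable(self, panel):
        pwm = panel["DREF"]
        assert score_window(pwm, "ACGTNCGT") is None


class TestScoreDistribution:
    def test_width_one_equals_reweighted_background(self):
        pwm = PWM("w1", np.array([[0.7, 0.1, 0.1, 0.1]]))
        d = score_distribution(pwm)
        assert len(d.support) <= 4
        assert d.pmf.sum() == pytest.approx(1.0)
        # the consensus score carries exactly the background probability of A
        top = d.pmf[-1]
        assert top == pytest.approx(0.25)

    @pytest.mark.parametrize("motif", ["DREF"])
    def test_matches_full_enumeration(self, panel, motif):
        pwm = panel[motif]
        assert pwm.width <= 8
        ints = pwm.int_scores()
        codes = np.array(list(itertools.product(range(4), repeat=pwm.width)))
        scores = ints[np.arange(pwm.width), codes].sum(axis=1)
        probs = pwm.background[codes].prod(axis=1)
        d = score_distribution(pwm)
        for s in np.unique(scores):
            assert probs[scores >= s].sum() == pytest.approx(d.sf(int(s)), abs=1e-12)

    def test_small_random_pwm_enumeration(self):
        rng = np.random.default_rng(4)
        probs = rng.dirichlet([1, 1, 1, 1], size=5)
        pwm = PWM("rand", probs)
        ints = pwm.int_scores()
        codes = np.array(list(itertools.product(range(4), repeat=5)))
        scores = ints[np.arange(5), codes].sum(axis=1)
        d = score_distribution(pwm)
        assert d.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        s_med = int(np.median(scores))
        enum_tail = pwm.background[codes].prod(axis=1)[scores >= s_med].sum()
        assert enum_tail == pytest.approx(d.sf(s_med), abs=1e-12)


class TestBestHitPvalue:
    def test_sequence_shorter_than_width_raises(self, panel):
        with pytest.raises(ValueError, match="width"):
            best_hit_pvalue(panel["RAM"], "ACGT")

    def test_consensus_site_pvalue_matches_enumeration(self, panel):
        # p_site of the maximum score is the background probability of the
        # consensus word (unique argmax per column)
        pwm = panel["DREF"]
        hit = best_hit_pvalue(pwm, pwm.consensus)
        assert hit.p_site == pytest.approx(0.25 ** pwm.width, rel=1e-9)
        assert hit.n_windows == 2

    def test_sidak_composition_over_windows(self, panel):
        pwm = panel["DREF"]
        seq = pwm.consensus + "AC"  # 10 bp -> 3 positions x 2 strands
        hit = best_hit_pvalue(pwm, seq)
        assert hit.n_windows == 6
        assert hit.p_sequence == pytest.approx(1 - (1 - hit.p_site) ** 6)

    def test_all_n_region_is_unscorable_not_one(self, panel):
        assert best_hit_pvalue(panel["DREF"], "N" * 50) is None

    def test_n_windows_shrink_with_embedded_n(self, panel):
        pwm = panel["DREF"]
        seq = "ACGTACGTACGT" + "N" + "ACGTACGTACGT"
        hit = best_hit_pvalue(pwm, seq)
        assert hit.n_windows == 2 * 10  # 5 clean windows per side, both strands


class TestShuffle:
    def test_homopolymer_is_invariant(self):
        assert shuffle_sequence("AAAA", seed=1) == "AAAA"

    def test_base_counts_preserved(self):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 300)
        shuf = shuffle_sequence(seq, seed=9)
        assert sorted(shuf) == sorted(seq)

    def test_permutations_uniform_chi_square(self):
        rng = np.random.default_rng(6)
        counts = {}
        n = 2400
        for _ in range(n):
            s = shuffle_sequence("ACGT", rng)
            counts[s] = counts.get(s, 0) + 1
        perms = ["".join(p) for p in itertools.permutations("ACGT")]
        assert set(counts) <= set(perms)
        observed = np.array([counts.get(p, 0) for p in perms])
        chi2 = ((observed - n / 24) ** 2 / (n / 24)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=23)

    def test_dinucleotide_shuffle_preserves_doublets(self):
        rng = np.random.default_rng(7)
        seq = random_seq(rng, 120)
        shuf = shuffle_sequence(seq, seed=3, method="dinuc")

        def doublets(s):
            out = {}
            for a, b in zip(s, s[1:]):
                out[a + b] = out.get(a + b, 0) + 1
            return out

        assert doublets(shuf) == doublets(seq)


class TestCalibration:
    def test_default_candidates_include_1e4(self, probe_pwm):
        rng = np.random.default_rng(8)
        regions = [random_seq(rng, 60) for _ in range(20)]
        res = calibrate_threshold(probe_pwm, regions, n_shuffles=2, seed=1)
        assert 1e-4 in res.candidate_thresholds
        assert res.chosen_threshold in res.candidate_thresholds

    def test_pure_noise_ties_to_most_stringent(self, probe_pwm):
        # regions are themselves scrambles of background: no signal anywhere
        rng = np.random.default_rng(9)
        regions = [random_seq(rng, 150) for _ in range(60)]
        res = calibrate_threshold(
            probe_pwm, regions, n_shuffles=3, candidates=(1e-4, 1e-5, 1e-6), seed=2
        )
        for t, diff in zip(res.candidate_thresholds, res.differences):
            band = 3 * math.sqrt(2 * t * (1 - t) / 60)
            assert abs(diff) <= band + 1e-12
        # strictly-zero differences at stringent candidates tie; most stringent wins
        assert res.chosen_threshold == min(res.candidate_thresholds)

    def test_scramble_false_call_rate_tracks_threshold(self, probe_pwm):
        # on background-composition regions, the fraction of scrambles called
        # at threshold t estimates t itself (sequence-level p ~ Uniform)
        rng = np.random.default_rng(10)
        regions = [random_seq(rng, 150) for _ in range(300)]
        res = calibrate_threshold(
            probe_pwm, regions, n_shuffles=8, candidates=(1e-1, 1e-2), seed=4
        )
        t = 1e-1
        n = 300 * 8
        sd = math.sqrt(t * (1 - t) / n)
        assert abs(res.frac_scrambled[0] - t) <= 3 * sd + 0.01


class TestScanRegions:
    def test_empty_motif_list_gives_zero_columns(self):
        matrix = scan_regions([], [("r1", "ACGTACGT")], {})
        assert matrix.present.shape == (1, 0)

    def test_consensus_with_short_padding_called_at_1e4(self, panel):
        # an 8-bp motif can only clear p < 1e-4 in a short sequence: the
        # best-hit p has a floor of 1-(1-0.25^w)^m
        pwm = panel["DREF"]
        region = pwm.consensus + "AC"
        matrix = scan_regions([pwm], [("r", region)], {"DREF": 1e-4})
        assert matrix.present[0, 0]

    def test_presence_invariant_to_duplicated_site(self, panel):
        pwm = panel["RAM"]
        rng = np.random.default_rng(11)
        pad = random_seq(rng, 60)
        one = pad + pwm.consensus + pad
        two = pad + pwm.consensus + pwm.consensus + pad
        m = scan_regions([pwm], [("one", one), ("two", two)], {"RAM": 1e-3})
        assert m.present[0, 0] and m.present[1, 0]

    def test_reverse_complement_symmetry(self, panel):
        rng = np.random.default_rng(12)
        pwms = [panel["E2F"], panel["RAM"]]
        thresholds = {"E2F": 1e-3, "RAM": 1e-3}
        regions = []
        for i in range(30):
            s = random_seq(rng, 120)
            if i % 3 == 0:
                s = s[:40] + pwms[i % 2].consensus + s[40:]
            regions.append((f"r{i}", s))
        rc = [(rid, s.translate(str.maketrans("ACGT", "TGCA"))[::-1]) for rid, s in regions]
        m1 = scan_regions(pwms, regions, thresholds)
        m2 = scan_regions(pwms, rc, thresholds)
        assert np.array_equal(m1.present, m2.present)

    def test_unscorable_region_flagged_and_false(self, panel):
        m = scan_regions([panel["DREF"]], [("bad", "N" * 40)], {"DREF": 1e-2})
        assert not m.ok[0]
        assert not m.present[0, 0]

    def test_presence_round_trip(self, tmp_path, panel):
        rng = np.random.default_rng(13)
        regions = [(f"r{i}", random_seq(rng, 60)) for i in range(5)]
        m = scan_regions([panel["DREF"]], regions, {"DREF": 1e-2})
        path = tmp_path / "presence.tsv"
        write_presence(path, m)
        back = read_presence(path)
        assert back.region_ids == m.region_ids
        assert np.array_equal(back.present, m.present)
        assert np.array_equal(back.ok, m.ok)


class TestMemeFormat:
    def test_round_trip(self, tmp_path, panel):
        path = tmp_path / "panel.meme"
        write_meme(path, list(panel.values()))
        back = read_meme(path)
        assert [p.motif_id for p in back] == list(panel)
        for orig, rt in zip(panel.values(), back):
            assert np.allclose(orig.probs, rt.probs, atol=1e-6)


def test_null_pvalues_approximately_uniform_small(probe_pwm):
    """Spot check of p-value uniformity at modest n (the full-size check
    lives with the acceptance suite)."""
    rng = np.random.default_rng(14)
    seqs = [random_seq(rng, 200) for _ in range(400)]
    ps = best_hit_pvalues(probe_pwm, seqs)
    assert stats.kstest(ps, "uniform").pvalue > 0.01
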