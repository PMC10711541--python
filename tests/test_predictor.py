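"""PWM training, octamer background, candidate scoring and prediction."""

import math
from collections import defaultdict

import numpy as np
import pytest

from bpscan import (
    GenomeAssembly,
    PWM,
    canonical_tna_fraction,
    consensus_sequence,
    distance_summary,
    predict_branch_points,
    score_candidate,
)
from bpscan.annotation import IntronRecord
from bpscan.genome import reverse_complement
from bpscan.predictor import OctamerBackground

BASES = "ACGT"
UNIFORM = np.full(4, 0.25)


def _intron_genome(intron_seq, pad=60, strand="+"):
    """A single intron embedded in uniform-random flanks."""
    import zlib

    rng = np.random.default_rng(zlib.crc32(intron_seq.encode()))
    flank = lambda: "".join("ACGT"[i] for i in rng.integers(0, 4, size=pad))
    chrom_seq = flank() + intron_seq + flank()
    genome = GenomeAssembly({"c": chrom_seq})
    intron = IntronRecord("c", pad, pad + len(intron_seq), strand, "g")
    return genome, intron


class TestPWM:
    def test_single_heptamer_training_pseudocount(self):
        pwm = PWM.train(["TTTTAAC"])
        assert pwm.probs[3, BASES.index("T")] == pytest.approx((1 + 1) / (1 + 4))
        assert pwm.probs[3, BASES.index("A")] == pytest.approx(1 / 5)

    @pytest.mark.parametrize("n", [1, 5, 50])
    def test_identical_training_set_max_entry(self, n):
        pwm = PWM.train(["TGCTAAC"] * n)
        assert pwm.probs.max(axis=1) == pytest.approx(np.full(7, (n + 1) / (n + 4)))

    @pytest.mark.parametrize("bad", ["TTTT", "TTTTAAX", "TTTTAACC"])
    def test_invalid_heptamer_rejected(self, bad):
        with pytest.raises(ValueError):
            PWM.train([bad])

    def test_default_pwm_has_published_consensus(self):
        assert PWM.default().consensus() == "nnyTrAy"

    def test_tsv_round_trip(self, tmp_path):
        pwm = PWM.train(["TTTTAAC", "CTCTGAT"])
        pwm.to_tsv(tmp_path / "pwm.tsv")
        back = PWM.from_tsv(tmp_path / "pwm.tsv")
        assert np.allclose(back.probs, pwm.probs, atol=1e-6)


class TestOctamerBackground:
    def test_single_octamer_intron_pseudocount_arithmetic(self):
        genome, intron = _intron_genome("ACGTACGT")
        bg = OctamerBackground.estimate([intron], genome, window=50, bin_width=50)
        assert bg.n_bins == 1
        code = sum(BASES.index(b) * 4 ** (7 - i) for i, b in enumerate("ACGTACGT"))
        assert bg.bin_freq[0, code] == pytest.approx((1 + 1) / (4**8 + 1))
        # any unseen octamer carries only the pseudocount
        assert bg.bin_freq[0, (code + 1) % 4**8] == pytest.approx(1 / (4**8 + 1))

    def test_all_n_intron_contributes_nothing(self):
        genome = GenomeAssembly({"c": "A" * 20 + "N" * 30 + "ACGTACGTACGT" + "A" * 20})
        n_intron = IntronRecord("c", 20, 50, "+", "g")
        real = IntronRecord("c", 50, 62, "+", "g")
        both = OctamerBackground.estimate([n_intron, real], genome, window=16, bin_width=8)
        solo = OctamerBackground.estimate([real], genome, window=16, bin_width=8)
        assert np.array_equal(both.bin_freq, solo.bin_freq)
        with pytest.raises(ValueError, match="no usable introns"):
            OctamerBackground.estimate([n_intron], genome, window=16, bin_width=8)

    def test_bin_frequencies_match_brute_force_counter(self, small_sim):
        introns = small_sim["introns"][:100]
        genome = small_sim["genome"]
        window, bw = 60, 10
        bg = OctamerBackground.estimate(introns, genome, window=window, bin_width=bw)
        counts = [defaultdict(int) for _ in range(bg.n_bins)]
        totals = [0] * bg.n_bins
        for intron in introns:
            seq = intron.sequence(genome)
            n = len(seq)
            w = min(window, n)
            for j in range(n - 7):
                o = seq[j : j + 8]
                if "N" in o:
                    continue
                d3 = n - j - 8
                if j >= n - w and d3 < window:
                    counts[d3 // bw][o] += 1
                    totals[d3 // bw] += 1
        rng = np.random.default_rng(0)
        for b in range(bg.n_bins):
            denom = totals[b] + 4**8
            for o, c in list(counts[b].items())[:50]:
                code = sum(BASES.index(x) * 4 ** (7 - i) for i, x in enumerate(o))
                assert bg.bin_freq[b, code] == pytest.approx((c + 1) / denom)
            absent = "".join("ACGT"[i] for i in rng.integers(0, 4, size=8))
            if absent not in counts[b]:
                code = sum(BASES.index(x) * 4 ** (7 - i) for i, x in enumerate(absent))
                assert bg.bin_freq[b, code] == pytest.approx(1 / denom)


def _brute_score(hept, context, pwm, q, bg, lam):
    """Independent recomputation of the two-component log-odds."""
    s = sum(
        math.log2(pwm.probs[k, BASES.index(b)] / q[BASES.index(b)])
        for k, b in enumerate(hept)
    )
    m = len(context)
    for j in range(m - 7):
        o = context[j : j + 8]
        if "N" in o:
            continue
        d3 = m - j - 8
        if bg is None or d3 >= bg.window:
            continue
        code = 0
        for ch in o:
            code = code * 4 + BASES.index(ch)
        s += lam * math.log2(bg.bin_freq[d3 // bg.bin_width, code] / bg.genome_freq[code])
    return s


class TestScoring:
    def test_pwm_equal_to_background_scores_zero(self):
        pwm = PWM(np.full((7, 4), 0.25))
        assert score_candidate("ACGTACG", "", pwm, None, UNIFORM, lam=0.0) == pytest.approx(0.0)

    def test_trained_pwm_scores_its_own_heptamer(self):
        pwm = PWM.train(["TTTTAAC"])
        s = score_candidate("TTTTAAC", "", pwm, None, UNIFORM, lam=0.0)
        assert s == pytest.approx(7 * math.log2(0.4 / 0.25))

    def test_n_in_heptamer_rejected(self):
        pwm = PWM.train(["TTTTAAC"])
        with pytest.raises(ValueError, match="undetermined"):
            score_candidate("TTNTAAC", "", pwm, None, UNIFORM)

    def test_matches_brute_force_on_random_candidates(self, small_sim):
        genome = small_sim["genome"]
        introns = small_sim["introns"]
        bg = OctamerBackground.estimate(introns[:80], genome, window=100, bin_width=10)
        pwm = PWM.default()
        q = genome.base_frequencies()
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 50:
            intron = introns[int(rng.integers(0, len(introns)))]
            seq = intron.sequence(genome)
            n = len(seq)
            d = int(rng.integers(9, min(150, n - 7)))
            hept = seq[n - d - 5 : n - d + 2]
            context = seq[n - d + 1 :]
            if "N" in hept:
                continue
            got = score_candidate(hept, context, pwm, bg, q, lam=1.0)
            assert got == pytest.approx(_brute_score(hept, context, pwm, q, bg, 1.0), abs=1e-9)
            checked += 1

    def test_predictor_best_equals_exhaustive_candidate_scan(self, small_sim):
        """The suffix-sum fast path agrees with scoring every candidate directly."""
        genome = small_sim["genome"]
        introns = small_sim["introns"][:5]
        bg = OctamerBackground.estimate(small_sim["introns"][:80], genome, window=100, bin_width=10)
        pwm = PWM.default()
        q = genome.base_frequencies()
        preds = predict_branch_points(introns, genome, pwm, bg=bg, lam=1.0, q=q)
        for p, intron in zip(preds, introns):
            seq = intron.sequence(genome)
            n = len(seq)
            best = max(
                (
                    _brute_score(seq[n - d - 5 : n - d + 2], seq[n - d + 1 :], pwm, q, bg, 1.0),
                    -d,
                )
                for d in range(9, min(150, n - 7) + 1)
                if "N" not in seq[n - d - 5 : n - d + 2]
            )
            assert p.score == pytest.approx(best[0], abs=1e-9)
            assert p.distance == -best[1]


class TestPrediction:
    def test_ties_break_toward_the_acceptor(self):
        # a flat PWM scores every candidate identically; nearest wins
        genome, intron = _intron_genome("A" * 200)
        pwm = PWM(np.full((7, 4), 0.25))
        preds = predict_branch_points([intron], genome, pwm, lam=0.0, q=UNIFORM)
        assert preds.predictions[0].distance == 9

    def test_intron_too_short_for_search_window_is_unpredicted(self):
        genome, intron = _intron_genome("ACGTACGTACGTAC")  # 14 bases
        pwm = PWM.default()
        preds = predict_branch_points([intron], genome, pwm, lam=0.0)
        assert len(preds) == 0
        assert preds.unpredicted == ["c:61-74:+"]

    def test_score_and_coordinates_are_strand_symmetric(self):
        rng = np.random.default_rng(17)
        intron_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=160))
        genome_fwd, intron_fwd = _intron_genome(intron_seq, strand="+")
        L = genome_fwd.length("c")
        genome_rev = GenomeAssembly({"c": reverse_complement(genome_fwd.sequence("c"))})
        intron_rev = IntronRecord("c", L - intron_fwd.end, L - intron_fwd.start, "-", "g")
        pwm = PWM.default()
        p_fwd = predict_branch_points([intron_fwd], genome_fwd, pwm, lam=0.0, q=UNIFORM).predictions[0]
        p_rev = predict_branch_points([intron_rev], genome_rev, pwm, lam=0.0, q=UNIFORM).predictions[0]
        assert p_rev.score == pytest.approx(p_fwd.score)
        assert p_rev.heptamer == p_fwd.heptamer
        assert p_rev.distance == p_fwd.distance
        assert p_rev.bp_pos == L - p_fwd.bp_pos + 1

    def test_predicted_heptamers_reextract_from_the_genome(self, small_sim):
        genome = small_sim["genome"]
        pwm = PWM(small_sim["cfg"].generative_pwm)
        preds = predict_branch_points(small_sim["introns"][:200], genome, pwm, lam=0.0)
        assert len(preds) > 0
        for p in preds:
            lo = min(p.heptamer_positions) - 1
            hi = max(p.heptamer_positions)
            raw = genome.sequence(p.chrom)[lo:hi]
            if p.strand == "-":
                raw = reverse_complement(raw)
            assert raw == p.heptamer


class TestSummaries:
    def test_uniform_predictions_consensus_is_the_heptamer(self):
        assert consensus_sequence(["TTTTAAC"] * 4) == "TTTTAAC"

    def test_even_pyrimidine_split_codes_as_y(self):
        assert consensus_sequence(["TTTCAAC", "TTTTAAC"])[3] == "y"

    def test_mixed_position_codes_as_n(self):
        hepts = ["ATTTAAC", "CTTTAAC", "GTTTAAC", "TTTTAAC"]
        assert consensus_sequence(hepts)[0] == "n"

    def test_synthetic_predictions_keep_conserved_t4_a6(self, small_sim):
        pwm = PWM(small_sim["cfg"].generative_pwm)
        preds = predict_branch_points(
            small_sim["introns"], small_sim["genome"], pwm, lam=0.0
        )
        cons = consensus_sequence(preds)
        assert cons[3] == "T" and cons[5] == "A"
        assert canonical_tna_fraction(preds) > 0.8

    @pytest.mark.parametrize(
        "hepts,expected",
        [
            (["TTTTAAC"], 1.0),
            (["CTTTGAC"], 1.0),
            (["AAAAAAA"], 0.0),
            (["TTTTAAC", "AAAAAAA"], 0.5),
        ],
    )
    def test_canonical_tna_fraction(self, hepts, expected):
        assert canonical_tna_fraction(hepts) == pytest.approx(expected)

    def test_distance_summary_median(self):
        from bpscan.predictor import BranchPointPrediction

        def pred(d):
            return BranchPointPrediction("i", "c", "+", 100, d, "TTTTAAC", 0.0, tuple(range(94, 101)))

        assert distance_summary([pred(26)] * 3)["median"] == 26
        assert distance_summary([pred(14), pred(27), pred(145)])["median"] == 27

    def test_empty_prediction_set_rejected(self):
        with pytest.raises(ValueError):
            consensus_sequence([])
        with pytest.raises(ValueError):
            distance_summary([])
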