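import itertools
import math

import numpy as np
import pytest

from consites.intervals import GenomicInterval, Peak
from consites.pwm import (
    PWMModel,
    best_site_in_peak,
    best_sites_in_peaks,
    exact_pvalue_table,
    read_pwm,
    reverse_complement,
    scan_sequence,
    score_window,
)


def brute_force_tail(pwm: PWMModel, granularity: float):
    """Independent oracle: enumerate all 4^w sequences under the background."""
    lom = pwm.log_odds()
    w = pwm.width
    scores, probs = [], []
    for seq in itertools.product(range(4), repeat=w):
        scores.append(sum(lom[i, b] for i, b in enumerate(seq)))
        probs.append(math.prod(pwm.background[b] for b in seq))
    order = np.argsort(scores)[::-1]
    scores = np.array(scores)[order]
    probs = np.array(probs)[order]
    return scores, np.cumsum(probs)  # tail prob of >= scores[i]


class TestScoreWindow:
    def test_closed_form_single_column(self):
        pwm = PWMModel(np.array([[1.0, 0, 0, 0]]), pseudocount=0.0)
        assert score_window(pwm, "A") == pytest.approx(math.log(1 / 0.25))

    def test_pseudocount_formula(self):
        pwm = PWMModel(np.array([[1.0, 0, 0, 0]]), pseudocount=0.01)
        assert score_window(pwm, "C") == pytest.approx(math.log(0.01 / 0.26))

    def test_palindromic_pwm_strand_symmetric(self, rng):
        # row i reversed-complemented equals row w-1-i => palindromic matrix,
        # so every sequence scores the same on both strands
        probs = np.array([[0.4, 0.1, 0.2, 0.3], [0.15, 0.35, 0.25, 0.25],
                          [0.25, 0.25, 0.35, 0.15], [0.3, 0.2, 0.1, 0.4]])
        pwm = PWMModel(probs)
        for _ in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 4))
            assert score_window(pwm, seq, "+") == pytest.approx(score_window(pwm, seq, "-"))

    def test_n_invalidates_window(self):
        pwm = PWMModel(np.array([[1.0, 0, 0, 0]]))
        assert score_window(pwm, "N") == -np.inf

    def test_length_mismatch(self):
        pwm = PWMModel(np.array([[1.0, 0, 0, 0]]))
        with pytest.raises(ValueError):
            score_window(pwm, "AA")


class TestExactPvalueTable:
    def test_width1_uniform(self):
        pwm = PWMModel(np.array([[0.7, 0.1, 0.1, 0.1]]))
        table = exact_pvalue_table(pwm)
        best = score_window(pwm, "A")
        assert table.pvalue(best) == pytest.approx(0.25)
        assert table.pvalue(-np.inf) == 1.0
        assert table.tail[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("width", [1, 2, 3, 5, 8])
    def test_matches_bruteforce(self, width, rng):
        g = 1e-3
        probs = rng.dirichlet(np.ones(4), size=width)
        bg = rng.dirichlet(np.full(4, 5.0))
        pwm = PWMModel(probs, bg)
        table = exact_pvalue_table(pwm, g)
        scores, tails = brute_force_tail(pwm, g)
        step = max(1, len(scores) // 64)
        # each position rounds to the lattice independently, so the total
        # discretization error is bounded by width * granularity / 2
        m = g * (width / 2 + 1)
        for s, t in zip(scores[::step], tails[::step]):
            assert table.pvalue(s - m) >= t - 1e-9
            assert table.pvalue(s + m) <= t + 1e-9

    def test_tail_non_increasing(self, score_table):
        assert (np.diff(score_table.tail) <= 1e-12).all()


class TestBestSite:
    def test_implanted_consensus_found(self, core_pwm, rng):
        cons = core_pwm.consensus()
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        seq = bg[:50] + cons + bg[66:]
        peak = Peak(GenomicInterval("chr1", 1000, 1200), "K562")
        site = best_site_in_peak(core_pwm, seq, peak)
        assert site is not None
        assert site.interval.start == 1050
        assert site.interval.strand == "+"
        assert site.cell_line == "K562"

    def test_tie_breaks_leftmost(self, core_pwm, rng):
        cons = core_pwm.consensus()
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        seq = bg[:10] + cons + bg[26:50] + cons + bg[66:]
        peak = Peak(GenomicInterval("chr1", 0, 200))
        site = best_site_in_peak(core_pwm, seq, peak)
        assert site.interval.start == 10

    def test_background_call_rate_matches_cutoff(self, core_pwm, score_table, rng):
        """Over random 200-bp peaks the per-peak hit chance follows the cutoff.

        With ~2*(200-w+1) tests per peak at tail probability alpha, the
        family-wise hit rate is ~1-(1-alpha)^(2*185); overlapping windows
        correlate mildly, so a generous Monte-Carlo band is used.
        """
        alpha = score_table.pvalue(score_table.score_threshold(0.0005))
        expected = 1 - (1 - alpha) ** (2 * 185)
        hits = 0
        n = 1000
        peaks = [Peak(GenomicInterval("chr1", i * 200, (i + 1) * 200)) for i in range(n)]
        genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, 200 * n))}
        calls = best_sites_in_peaks(core_pwm, peaks, genome, 0.0005, score_table)
        hits = sum(1 for c in calls if c is not None)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) < 5 * se + 0.02

    def test_monotone_in_cutoff(self, core_pwm, score_table, rng):
        genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, 40_000))}
        peaks = [Peak(GenomicInterval("chr1", i * 200, (i + 1) * 200)) for i in range(200)]
        n_calls = []
        for cutoff in (1e-5, 1e-4, 5e-4, 5e-3):
            calls = best_sites_in_peaks(core_pwm, peaks, genome, cutoff, score_table)
            n_calls.append(sum(c is not None for c in calls))
        assert n_calls == sorted(n_calls)

    def test_batch_equals_single(self, core_pwm, score_table, rng):
        genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))}
        cons = core_pwm.consensus()
        g = genome["chr1"]
        genome["chr1"] = g[:505] + cons + g[521:]
        peaks = [Peak(GenomicInterval("chr1", i * 200, (i + 1) * 200)) for i in range(50)]
        batch = best_sites_in_peaks(core_pwm, peaks, genome, 0.0005, score_table)
        for p, b in zip(peaks, batch):
            seq = genome["chr1"][p.interval.start : p.interval.end]
            single = best_site_in_peak(core_pwm, seq, p, 0.0005, score_table)
            if single is None:
                assert b is None
            else:
                assert b.interval == single.interval
                assert b.score == pytest.approx(single.score)


def test_read_pwm_counts_normalized(tmp_path):
    p = tmp_path / "m.pwm"
    p.write_text("# A C G T\n10 0 0 0\n5 5 0 0\n")
    pwm = read_pwm(p)
    assert pwm.width == 2
    assert pwm.probs[0, 0] == pytest.approx(1.0)
    assert pwm.probs[1, 0] == pytest.approx(0.5)


def test_scan_sequence_reverse_strand_consistency(core_pwm, rng):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
    fwd, rev = scan_sequence(core_pwm, seq)
    # minus-strand score at offset i equals scoring the revcomp window forward
    for i in (0, 10, 44):
        window = seq[i : i + core_pwm.width]
        assert rev[i] == pytest.approx(score_window(core_pwm, window, "-"))
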