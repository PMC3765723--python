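import numpy as np
import pytest

from consites.fullspectrum import (
    build_composite_motif,
    extract_extended_sequences,
    kmer_to_string,
    motif_prevalence,
    positional_kmer_counts,
)
from consites.intervals import GenomicInterval
from consites.pwm import reverse_complement


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestExtract:
    def test_geometry(self, rng):
        genome = {"chr1": random_seq(rng, 1000)}
        sites = [GenomicInterval("chr1", 500, 516, "+")]
        (seq,) = extract_extended_sequences(sites, genome, flank=30)
        assert len(seq) == 76
        assert seq[30:46] == genome["chr1"][500:516]

    def test_minus_strand_reverse_complemented(self, rng):
        genome = {"chr1": random_seq(rng, 1000)}
        sites = [GenomicInterval("chr1", 500, 516, "-")]
        (seq,) = extract_extended_sequences(sites, genome, flank=30)
        assert seq == reverse_complement(genome["chr1"][470:546])

    def test_contig_edge_skipped_with_warning(self, rng):
        genome = {"chr1": random_seq(rng, 1000)}
        sites = [GenomicInterval("chr1", 10, 26, "+"), GenomicInterval("chr1", 500, 516, "+")]
        with pytest.warns(UserWarning, match="skipped"):
            seqs = extract_extended_sequences(sites, genome, flank=30)
        assert len(seqs) == 1


class TestPositionalCounts:
    def test_window_and_alphabet_dimensions(self, rng):
        seqs = [random_seq(rng, 76) for _ in range(5)]
        counts = positional_kmer_counts(seqs, k=5)
        assert counts.positions == 72  # 30 + 30 + 16 - 5 + 1
        assert counts.counts.shape[1] == 1024  # 4^5 possible words

    def test_identical_sequences_fill_cells(self, rng):
        seq = random_seq(rng, 76)
        counts = positional_kmer_counts([seq] * 3, k=5)
        occupied = counts.counts[counts.counts > 0]
        assert (occupied == 3).all()

    def test_one_kmer_per_position_per_sequence(self, rng):
        seqs = [random_seq(rng, 76) for _ in range(7)]
        counts = positional_kmer_counts(seqs, k=5)
        assert (counts.counts.sum(axis=1) == 7).all()

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError):
            positional_kmer_counts(["ACGTACGT", "ACGT"], k=3)


class TestComposite:
    def test_shared_flank_word_reproduced(self):
        # every sequence carries the same left flank; composite must spell it
        word = "ACGTGCATTGCAGGTCAAGCTTACGGATCT"  # 30-bp left flank
        seqs = [word + "C" * 16 + "A" * 30 for _ in range(10)]
        counts = positional_kmer_counts(seqs, k=5)
        comp = build_composite_motif(counts, "left", top_n=50)
        called = "".join("ACGT"[i] for i in np.argmax(comp.matrix[:30], axis=1))
        assert called == word

    def test_top1_equals_best_kmer_profile(self, rng):
        seqs = [random_seq(rng, 76) for _ in range(20)]
        counts = positional_kmer_counts(seqs, k=5)
        comp = build_composite_motif(counts, "right", top_n=1)
        assert len(comp.contributing_kmers) == 1
        word, _ = comp.contributing_kmers[0]
        # the single word's bases dominate wherever it was counted
        sub = counts.counts[list(counts.side_positions("right"))]
        best_pos = int(np.argmax(sub.max(axis=1)))
        assert comp.matrix.shape == (30, 4)

    def test_order_invariance(self, rng):
        seqs = [random_seq(rng, 76) for _ in range(30)]
        c1 = build_composite_motif(positional_kmer_counts(seqs, k=5), "left", 10)
        c2 = build_composite_motif(positional_kmer_counts(seqs[::-1], k=5), "left", 10)
        assert np.allclose(c1.matrix, c2.matrix)

    def test_implanted_repeat_recovered(self, rng):
        """A GGAGGAGGAGG-like right-flank implant dominates the ranking."""
        implant = "GGAGGAGGAGG"
        seqs = []
        for i in range(200):
            s = random_seq(rng, 76)
            if i < 120:  # 60% of sequences
                s = s[:50] + implant + s[61:]
            seqs.append(s)
        counts = positional_kmer_counts(seqs, k=5)
        comp = build_composite_motif(counts, "right", top_n=5)
        for word, _ in comp.contributing_kmers[:3]:
            assert word in implant
        # dominant bases reconstruct the implant at its offsets
        cols = comp.matrix[50 - comp.offset_start : 61 - comp.offset_start]
        called = "".join("ACGT"[i] for i in np.argmax(cols, axis=1))
        assert called == implant

    def test_few_kmers_warns(self):
        seqs = ["A" * 76] * 3
        counts = positional_kmer_counts(seqs, k=5)
        with pytest.warns(UserWarning, match="using all"):
            build_composite_motif(counts, "left", top_n=50)


class TestPrevalence:
    def test_planted_fraction_recovered(self, core_pwm, rng):
        """Sequences implanted with the core at 15% score back ~0.15."""
        cons = core_pwm.consensus()
        n = 400
        k = 60  # 15%
        seqs = []
        for i in range(n):
            s = random_seq(rng, 76)
            if i < k:
                s = s[:30] + cons + s[46:]
            seqs.append(s)
        rng.shuffle(seqs)
        prev = motif_prevalence({"cls": seqs}, {"core": core_pwm}, 0.0005)
        frac = prev["cls"]["core"]
        assert abs(frac - 0.15) < 5 * np.sqrt(0.15 * 0.85 / n) + 0.01

    def test_absent_motif_near_false_positive_rate(self, core_pwm, rng):
        seqs = [random_seq(rng, 76) for _ in range(500)]
        prev = motif_prevalence({"cls": seqs}, {"core": core_pwm}, 0.0005)
        # anchored single-window test: FP rate ~ the cutoff itself
        assert prev["cls"]["core"] <= 0.01

    def test_empty_class_errors(self, core_pwm):
        with pytest.raises(ValueError):
            motif_prevalence({"cls": []}, {"core": core_pwm})


def test_kmer_to_string_roundtrip():
    assert kmer_to_string(0, 3) == "AAA"
    assert kmer_to_string(4 ** 3 - 1, 3) == "TTT"
    assert kmer_to_string(0b0110, 2) == "CG"  # 1*4 + 2
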