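import numpy as np
import pytest

from consites.conservation import (
    AlignmentBlock,
    conservation_summary,
    merge_blocks,
    read_maf,
    species_with_hit,
    write_maf,
)
from consites.intervals import GenomicInterval
from consites import synthetic as syn


def block(rows, start=100, chrom="chr1"):
    width = len(next(iter(rows.values())))
    ref_len = len(rows["hg19"].replace("-", ""))
    return AlignmentBlock(GenomicInterval(chrom, start, start + ref_len), "hg19", rows)


class TestMerge:
    def test_single_block_identity(self):
        b = block({"hg19": "ACGT", "mm10": "A-GT"})
        assert merge_blocks([b]) is b

    def test_concatenates_shared_species(self):
        b1 = block({"hg19": "ACGT", "mm10": "AC-T"}, start=100)
        b2 = block({"hg19": "GGCC", "mm10": "GGCC"}, start=104)
        m = merge_blocks([b1, b2])
        assert m.rows["mm10"] == "AC-TGGCC"
        assert (m.ref_interval.start, m.ref_interval.end) == (100, 108)

    def test_absent_species_gap_filled(self):
        b1 = block({"hg19": "ACGT", "mm10": "ACGT"}, start=100)
        b2 = block({"hg19": "GGCC"}, start=104)
        m = merge_blocks([b1, b2])
        assert m.rows["mm10"] == "ACGT----"

    def test_overlapping_blocks_rejected(self):
        b1 = block({"hg19": "ACGT"}, start=100)
        b2 = block({"hg19": "ACGT"}, start=102)
        with pytest.raises(ValueError, match="overlap"):
            merge_blocks([b1, b2])


class TestSpeciesWithHit:
    def test_reference_only(self, core_pwm, score_table, rng):
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 10))
        row = flank + core_pwm.consensus() + flank
        b = block({"hg19": row})
        assert species_with_hit(b, core_pwm, table=score_table) == 1

    def test_identical_species_all_hit(self, core_pwm, score_table, rng):
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 10))
        row = flank + core_pwm.consensus() + flank
        rows = {"hg19": row, **{f"sp{i}": row for i in range(4)}}
        b = block(rows)
        assert species_with_hit(b, core_pwm, table=score_table) == 5

    def test_short_row_cannot_hit(self, core_pwm, score_table):
        rows = {"hg19": core_pwm.consensus() + "ACGT", "frag": "ACGTACGT" + "-" * 12}
        b = block(rows)
        assert species_with_hit(b, core_pwm, table=score_table) == 1

    def test_bounded_by_row_count(self, core_pwm, score_table, rng):
        rows = {"hg19": core_pwm.consensus() + "AAAA"}
        for i in range(3):
            rows[f"sp{i}"] = "".join("ACGT"[j] for j in rng.integers(0, 4, 20))
        b = block(rows)
        assert species_with_hit(b, core_pwm, table=score_table) <= 4

    def test_gaps_do_not_change_gapfree_hit(self, core_pwm, score_table, rng):
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 10))
        clean = flank + core_pwm.consensus() + flank
        gapped = clean[:5] + "--" + clean[5:]
        b1 = block({"hg19": clean})
        b2 = AlignmentBlock(GenomicInterval("chr1", 100, 136), "hg19", {"hg19": gapped})
        assert species_with_hit(b1, core_pwm, table=score_table) == species_with_hit(
            b2, core_pwm, table=score_table
        )


class TestSummary:
    def test_mean_of_constant(self):
        s = conservation_summary({"a": [20, 20, 20]})
        assert s["a"]["mean"] == 20 and s["a"]["median"] == 20

    def test_identical_classes_identical_summaries(self):
        counts = [3, 9, 20, 41]
        s = conservation_summary({"a": counts, "b": list(counts)})
        sa = {k: v for k, v in s["a"].items() if k != "counts"}
        sb = {k: v for k, v in s["b"].items() if k != "counts"}
        assert sa == sb

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            conservation_summary({"a": []})


class TestMafIO:
    def test_roundtrip(self, tmp_path, core_pwm, rng):
        cfg = syn.GeneratorConfig(seed=5, n_species=6)
        genome, sites = syn.plant_motif_array(cfg, 10, core_pwm)
        blocks = syn.generate_alignments(cfg, sites, genome, retention_prob=1.0)
        path = tmp_path / "blocks.maf"
        write_maf(blocks, path)
        back = read_maf(path, "hg19")
        assert len(back) == len(blocks)
        for b1, b2 in zip(blocks, back):
            assert b1.rows == b2.rows
            assert b1.ref_interval.start == b2.ref_interval.start

    def test_split_then_merge_preserves_hits(self, core_pwm, score_table):
        cfg = syn.GeneratorConfig(seed=6, n_species=8)
        genome, sites = syn.plant_motif_array(cfg, 15, core_pwm)
        whole = syn.generate_alignments(cfg, sites, genome, retention_prob=0.5)
        for cut in (5, 13, 20):
            for w in whole:
                iv = w.ref_interval
                left = AlignmentBlock(
                    GenomicInterval(iv.chrom, iv.start, iv.start + cut),
                    "hg19",
                    {sp: s[:cut] for sp, s in w.rows.items()},
                )
                right = AlignmentBlock(
                    GenomicInterval(iv.chrom, iv.start + cut, iv.end),
                    "hg19",
                    {sp: s[cut:] for sp, s in w.rows.items()},
                )
                merged = merge_blocks([left, right])
                assert merged.rows == w.rows
                assert species_with_hit(
                    merged, core_pwm, table=score_table
                ) == species_with_hit(w, core_pwm, table=score_table)

    def test_generator_split_blocks_merge_cleanly(self, core_pwm, score_table):
        cfg = syn.GeneratorConfig(seed=6, n_species=8, block_split_prob=1.0)
        genome, sites = syn.plant_motif_array(cfg, 10, core_pwm)
        split = syn.generate_alignments(cfg, sites, genome, retention_prob=1.0)
        assert len(split) == 2 * len(sites)
        for i in range(0, len(split), 2):
            merged = merge_blocks(split[i : i + 2])
            # retention 1.0: every species keeps the motif
            assert species_with_hit(merged, core_pwm, table=score_table) == 8
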