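import numpy as np
import pytest

from consites import synthetic as syn
from consites.chiapet import sites_in_interactions
from consites.conservation import species_with_hit
from consites.domains import classify_interactions_by_domain
from consites.pwm import best_sites_in_peaks


def small_config(**kw):
    defaults = dict(
        seed=11,
        n_cell_lines=10,
        n_rad21_lines=3,
        n_smc3_lines=2,
        n_constitutive_sites=60,
        n_specific_sites_per_line=5,
        n_midfreq_sites=20,
        chrom_lengths={"chr1": 1_500_000, "chr2": 1_500_000},
        n_interaction_pairs=500,
    )
    defaults.update(kw)
    return syn.GeneratorConfig(**defaults)


class TestGenome:
    def test_deterministic_under_seed(self):
        cfg = small_config()
        g1 = syn.generate_genome(cfg)
        g2 = syn.generate_genome(cfg)
        assert g1 == g2

    def test_lengths_and_composition(self):
        cfg = small_config()
        g = syn.generate_genome(cfg)
        assert sum(len(s) for s in g.values()) == 3_000_000
        seq = g["chr1"]
        n = len(seq)
        for base in "ACGT":
            frac = seq.count(base) / n
            assert abs(frac - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)


class TestPeakSets:
    def test_full_generation_deterministic(self, core_pwm):
        cfg = small_config()
        out1 = syn.generate_peak_sets(cfg, syn.generate_genome(cfg), core_pwm)
        out2 = syn.generate_peak_sets(cfg, syn.generate_genome(cfg), core_pwm)
        assert out1[2] == out2[2]  # implanted genomes identical
        assert out1[0] == out2[0]  # peaks identical

    def test_specific_sites_are_singletons(self, core_pwm):
        cfg = small_config()
        peaks, _, _, truth = syn.generate_peak_sets(cfg, syn.generate_genome(cfg), core_pwm)
        assert sum(len(v) for v in truth.specific_sites.values()) == 50
        for line, sites in truth.specific_sites.items():
            for s in sites:
                covering = [
                    ln for ln, ps in peaks.items()
                    if any(
                        p.interval.chrom == s.chrom
                        and p.interval.start <= s.midpoint < p.interval.end
                        for p in ps
                    )
                ]
                assert covering == [line]

    def test_constitutive_occurrence_matches_dropout(self, core_pwm):
        cfg = small_config(n_cell_lines=56, dropout_rate=0.02)
        peaks, _, _, truth = syn.generate_peak_sets(cfg, syn.generate_genome(cfg), core_pwm)
        per_site = []
        for s in truth.constitutive_sites:
            n = sum(
                any(
                    p.interval.chrom == s.chrom
                    and p.interval.start <= s.midpoint < p.interval.end
                    for p in ps
                )
                for ps in peaks.values()
            )
            per_site.append(n)
        assert abs(np.mean(per_site) - 56 * 0.98) < 0.5

    def test_full_cohesin_colocation(self, core_pwm):
        cfg = small_config(cohesin_full_fraction=1.0, cohesin_none_fraction=0.0)
        _, cohesin, _, truth = syn.generate_peak_sets(cfg, syn.generate_genome(cfg), core_pwm)
        for s in truth.constitutive_sites:
            for prot, lines in cohesin.items():
                for line, ps in lines.items():
                    assert any(
                        p.interval.chrom == s.chrom
                        and p.interval.start <= s.midpoint < p.interval.end
                        for p in ps
                    ), (prot, line)

    def test_implants_scannable_at_planted_coordinates(self, core_pwm, score_table):
        cfg = small_config()
        peaks, _, genome, truth = syn.generate_peak_sets(cfg, syn.generate_genome(cfg), core_pwm)
        line = cfg.cell_lines()[0]
        called = best_sites_in_peaks(core_pwm, peaks[line], genome, 0.0005, score_table)
        called_ids = {c.identity() for c in called if c is not None}
        planted = {s.identity() for s in truth.constitutive_sites}
        covered = set()
        for p in peaks[line]:
            for s in truth.constitutive_sites:
                if (
                    p.interval.chrom == s.chrom
                    and p.interval.start <= s.midpoint < p.interval.end
                ):
                    covered.add(s.identity())
        assert len(covered & called_ids) / len(covered) > 0.98


class TestInteractions:
    def test_null_odds_ratio(self, rng):
        cfg = small_config(
            target_odds_ratio=1.0, n_interaction_pairs=2000,
            n_constitutive_sites=200, n_specific_sites_per_line=20,
        )
        truth = _site_only_truth(cfg)
        domains = syn.generate_domains(cfg)
        pairs = syn.generate_interactions(cfg, truth, domains)
        a, n1 = sites_in_interactions(truth.constitutive_sites, pairs)
        c, n0 = sites_in_interactions(truth.all_nonconstitutive_sites(), pairs)
        odds = (a / (n1 - a)) / (c / (n0 - c))
        se = np.sqrt(1 / a + 1 / (n1 - a) + 1 / c + 1 / (n0 - c))
        assert abs(np.log(odds)) < 3 * se  # planted null within Monte-Carlo CI

    def test_infeasible_odds_ratio_raises(self):
        cfg = small_config(target_odds_ratio=1000.0, nonconst_in_interaction_prob=0.5)
        truth = _site_only_truth(cfg)
        domains = syn.generate_domains(cfg)
        with pytest.raises(ValueError, match="infeasible"):
            syn.generate_interactions(cfg, truth, domains)

    def test_pair_count_and_determinism(self):
        cfg = small_config()
        truth1, truth2 = _site_only_truth(cfg), _site_only_truth(cfg)
        domains = syn.generate_domains(cfg)
        p1 = syn.generate_interactions(cfg, truth1, domains)
        p2 = syn.generate_interactions(cfg, truth2, domains)
        assert len(p1) == cfg.n_interaction_pairs
        assert p1 == p2

    def test_same_domain_fraction_recovered(self):
        cfg = small_config(n_interaction_pairs=3000, same_domain_fraction=0.8)
        truth = _site_only_truth(cfg)
        domains = syn.generate_domains(cfg)
        pairs = syn.generate_interactions(cfg, truth, domains)
        out = classify_interactions_by_domain(pairs, domains)
        f = out["fraction_same_domain"]
        n = sum(1 for lab in out["labels"] if lab in ("same-domain", "cross-domain"))
        assert abs(f - 0.8) < 4 * np.sqrt(0.8 * 0.2 / n)


class TestAlignments:
    def test_full_retention_all_species_hit(self, core_pwm, score_table):
        cfg = small_config(n_species=12)
        genome, sites = syn.plant_motif_array(cfg, 25, core_pwm)
        blocks = syn.generate_alignments(cfg, sites, genome, retention_prob=1.0)
        for b in blocks:
            assert species_with_hit(b, core_pwm, table=score_table) == 12

    def test_retention_probability_sets_mean(self, core_pwm, score_table):
        cfg = small_config(n_species=46)
        genome, sites = syn.plant_motif_array(cfg, 150, core_pwm)
        blocks = syn.generate_alignments(cfg, sites, genome, retention_prob=20 / 46)
        counts = [species_with_hit(b, core_pwm, table=score_table) for b in blocks]
        # reference always hits; 45 others retain at 20/46 plus a small
        # chance-hit floor in non-retained rows
        assert 18 < np.mean(counts) < 24


def _site_only_truth(cfg):
    """Truth with arithmetically spaced sites; no genome or peaks needed."""
    from consites.intervals import GenomicInterval

    truth = syn.SyntheticTruth(specific_sites={ln: [] for ln in cfg.cell_lines()})
    positions = syn._choose_site_positions(
        cfg,
        cfg.n_constitutive_sites
        + cfg.n_specific_sites_per_line * cfg.n_cell_lines
        + cfg.n_midfreq_sites,
        np.random.default_rng(cfg.seed + 9),
        16,
    )
    i = 0
    for _ in range(cfg.n_constitutive_sites):
        chrom, start = positions[i]
        truth.constitutive_sites.append(GenomicInterval(chrom, start, start + 16, "+"))
        i += 1
    for line in cfg.cell_lines():
        for _ in range(cfg.n_specific_sites_per_line):
            chrom, start = positions[i]
            truth.specific_sites[line].append(GenomicInterval(chrom, start, start + 16, "+"))
            i += 1
    for _ in range(cfg.n_midfreq_sites):
        chrom, start = positions[i]
        truth.midfreq_sites.append(GenomicInterval(chrom, start, start + 16, "+"))
        i += 1
    return truth


def test_fasta_roundtrip(tmp_path):
    cfg = small_config(chrom_lengths={"chrX": 12_000, "chrY": 15_000})
    g = syn.generate_genome(cfg)
    path = tmp_path / "genome.fa"
    syn.write_fasta(g, path)
    back = syn.load_fasta(path)
    assert back == g
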