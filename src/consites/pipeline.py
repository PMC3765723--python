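"""End-to-end orchestration of the analysis stages.

Stages mirror the analyses: simulate -> call-sites -> constitutive ->
annotate -> motifs -> conserve -> interactions -> domains.  Each stage
function takes a :class:`PipelineConfig` (defaults equal the survey's
published thresholds: 200-bp peaks, p <= 5e-4, >90% constitutive rule,
+-5 kb TSS window, +-2.5 kb CpG profile, +-200 bp co-factor margin,
30-bp flanks, k = 5, top 50 k-mers) plus in-memory inputs, returns its
results, and — when given an output directory — writes TSV/BED/JSON
artifacts along with a manifest recording parameters and output
checksums.  ``run_all`` chains everything on synthetic data, which makes
a full reproduction one function call.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotation, chiapet, conservation, constitutive, domains as domains_mod
from . import fullspectrum, synthetic
from .intervals import GenomicInterval, Peak, normalize_peak, write_bed
from .pwm import PWMModel, best_sites_in_peaks, exact_pvalue_table, read_pwm

__all__ = ["PipelineConfig", "PipelineResult", "run_all", "stage_call_sites",
           "stage_constitutive", "stage_interactions", "stage_domains",
           "stage_conservation", "stage_motifs"]


@dataclass
class PipelineConfig:
    """All thresholds of the analysis; defaults are the published values."""

    peak_length: int = 200
    pvalue_cutoff: float = 0.0005
    constitutive_fraction: float = 0.9
    tss_window: int = 5000
    cpg_halfwidth: int = 2500
    center_margin: int = 200
    flank: int = 30
    k: int = 5
    top_n_kmers: int = 50
    seed: int = 0
    pwm_path: str | None = None
    output_dir: str | None = None
    generator: synthetic.GeneratorConfig = field(default_factory=synthetic.GeneratorConfig)

    def __post_init__(self):
        for name in ("peak_length", "tss_window", "cpg_halfwidth", "center_margin",
                     "flank", "k", "top_n_kmers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.pvalue_cutoff < 1:
            raise ValueError("pvalue_cutoff must be in (0, 1)")
        if not 0 < self.constitutive_fraction < 1:
            raise ValueError("constitutive_fraction must be in (0, 1)")
        self.generator.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = synthetic.GeneratorConfig(**raw.pop("generator", {}))
        return cls(generator=gen, **raw)

    def load_pwm(self) -> PWMModel:
        if self.pwm_path:
            return read_pwm(self.pwm_path)
        return synthetic.ctcf_pwm()


@dataclass
class PipelineResult:
    """Everything the chained stages computed, for inspection or writing."""

    config: PipelineConfig
    genome: dict
    truth: synthetic.SyntheticTruth
    occurrence: constitutive.OccurrenceTable
    cctcf: set
    crad21: set
    csmc3: set
    class_labels: dict
    enrichment: dict
    type_counts: chiapet.PairTypeCounts
    domain_summary: dict
    conservation_summary: dict
    composites: dict
    stage_counts: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, params: dict, outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "parameters": params,
        "outputs": {str(p.name): _sha256(p) for p in outputs},
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, default=str))


def stage_call_sites(cfg: PipelineConfig, peaks_by_line: dict, genome: dict,
                     pwm: PWMModel | None = None, table=None) -> dict:
    """Best PWM site per normalized peak, per cell line."""
    pwm = pwm or cfg.load_pwm()
    if table is None:
        table = exact_pvalue_table(pwm)
    sites_by_line = {}
    for line, peaks in peaks_by_line.items():
        normed = [normalize_peak(p, cfg.peak_length) for p in peaks]
        called = best_sites_in_peaks(pwm, normed, genome, cfg.pvalue_cutoff, table)
        sites_by_line[line] = [s for s in called if s is not None]
    return sites_by_line


def stage_constitutive(cfg: PipelineConfig, ctcf_sites_by_line: dict,
                       rad21_sites_by_line: dict, smc3_sites_by_line: dict,
                       cohesin_peaks_by_line: dict):
    """Occurrence aggregation, constitutive calling, cohesin classification."""
    occ = constitutive.aggregate_sites(ctcf_sites_by_line.items())
    cctcf = constitutive.call_constitutive(occ, cfg.constitutive_fraction)
    occ_rad = constitutive.aggregate_sites(rad21_sites_by_line.items())
    crad21 = constitutive.call_constitutive(occ_rad, cfg.constitutive_fraction)
    occ_smc = constitutive.aggregate_sites(smc3_sites_by_line.items())
    csmc3 = constitutive.call_constitutive(occ_smc, cfg.constitutive_fraction)
    labels = constitutive.classify_sites(cctcf, crad21, csmc3, cohesin_peaks_by_line)
    return occ, cctcf, crad21, csmc3, labels


def stage_motifs(cfg: PipelineConfig, sites: list[GenomicInterval], genome: dict):
    """Extended sequences, positional k-mer counts, per-side composites."""
    seqs = fullspectrum.extract_extended_sequences(sites, genome, cfg.flank)
    counts = fullspectrum.positional_kmer_counts(seqs, cfg.k, flank=cfg.flank)
    left = fullspectrum.build_composite_motif(counts, "left", cfg.top_n_kmers)
    right = fullspectrum.build_composite_motif(counts, "right", cfg.top_n_kmers)
    return seqs, counts, {"left": left, "right": right}


def stage_conservation(cfg: PipelineConfig, blocks_by_class: dict, pwm=None, table=None):
    pwm = pwm or cfg.load_pwm()
    if table is None:
        table = exact_pvalue_table(pwm)
    counts = {
        cls: [conservation.species_with_hit(b, pwm, cfg.pvalue_cutoff, table) for b in blocks]
        for cls, blocks in blocks_by_class.items()
    }
    return conservation.conservation_summary(counts)


def stage_interactions(cfg: PipelineConfig, pairs, cctcf_sites, nonconst_sites):
    in1, n1 = chiapet.sites_in_interactions(cctcf_sites, pairs)
    in0, n0 = chiapet.sites_in_interactions(nonconst_sites, pairs)
    tab = chiapet.ContingencyTable2x2.from_totals(n1, in1, n0, in0)
    odds, p = chiapet.enrichment_test(tab)
    types = chiapet.fractional_type_counts(pairs, cctcf_sites, nonconst_sites)
    return {
        "cctcf_in": in1, "cctcf_total": n1, "nonconst_in": in0, "nonconst_total": n0,
        "odds_ratio": odds, "pvalue": p,
    }, types


def stage_domains(cfg: PipelineConfig, pairs, sites, domain_set: domains_mod.DomainSet):
    cls = domains_mod.classify_interactions_by_domain(pairs, domain_set)
    med = domain_set.median_length
    distances = []
    n_in = 0
    for s in sites:
        d = domain_set.containing(s.chrom, s.midpoint)
        if d is not None:
            n_in += 1
            distances.append(domains_mod.boundary_distance(s, d, med).standardized)
    kde = domains_mod.kde_distances(distances) if len(distances) >= 2 else None
    return {
        "interactions": cls,
        "fraction_sites_in_domains": n_in / len(sites) if sites else float("nan"),
        "standardized_distances": distances,
        "kde": kde,
    }


def run_all(cfg: PipelineConfig | None = None, outdir: str | None = None) -> PipelineResult:
    """Simulate a full dataset and run every stage on it."""
    cfg = cfg or PipelineConfig()
    gen = cfg.generator
    rng = np.random.default_rng(gen.seed)
    pwm = cfg.load_pwm()
    table = exact_pvalue_table(pwm)

    genome = synthetic.generate_genome(gen, rng)
    ctcf_peaks, cohesin_peaks, genome, truth = synthetic.generate_peak_sets(
        gen, genome, pwm, rng
    )

    ctcf_sites = stage_call_sites(cfg, ctcf_peaks, genome, pwm, table)
    rad21_sites = stage_call_sites(cfg, cohesin_peaks["Rad21"], genome, pwm, table)
    smc3_sites = stage_call_sites(cfg, cohesin_peaks["Smc3"], genome, pwm, table)

    cohesin_flat = {
        f"{prot}:{line}": [p.interval for p in peaks]
        for prot, by_line in cohesin_peaks.items()
        for line, peaks in by_line.items()
    }
    occ, cctcf, crad21, csmc3, labels = stage_constitutive(
        cfg, ctcf_sites, rad21_sites, smc3_sites, cohesin_flat
    )

    cctcf_ivs = [GenomicInterval(*ident) for ident in sorted(cctcf)]
    need = constitutive.min_required_count(occ.n_cell_lines, cfg.constitutive_fraction)
    nonconst_ivs = [
        GenomicInterval(*ident)
        for ident, lines in sorted(occ.entries.items())
        if len(lines) < need
    ]

    # motifs on the cohesin-classified constitutive sites
    cocohesin_ivs = [
        GenomicInterval(*ident) for ident, lab in sorted(labels.items())
        if lab == "cCTCF_cCohesin"
    ]
    _, _, composites = stage_motifs(cfg, cocohesin_ivs or cctcf_ivs, genome)

    # conservation: constitutive vs the 2-10-cell-line sampling frame
    lowfreq = [
        GenomicInterval(*ident)
        for ident, lines in sorted(occ.entries.items())
        if 2 <= len(lines) <= 10
    ]
    rng_cons = np.random.default_rng(gen.seed + 7)
    if len(lowfreq) > len(cctcf_ivs):
        pick = rng_cons.choice(len(lowfreq), size=len(cctcf_ivs), replace=False)
        lowfreq = [lowfreq[int(i)] for i in sorted(pick)]
    blocks = {
        "cCTCF": synthetic.generate_alignments(
            gen, cctcf_ivs, genome, gen.retention_prob_constitutive, rng
        ),
        "non_constitutive": synthetic.generate_alignments(
            gen, lowfreq, genome, gen.retention_prob_nonconstitutive, rng
        ),
    }
    cons = stage_conservation(cfg, blocks, pwm, table)

    domain_set = synthetic.generate_domains(gen, rng)
    pairs = synthetic.generate_interactions(gen, truth, domain_set, rng)
    enrich, types = stage_interactions(cfg, pairs, cctcf_ivs, nonconst_ivs)
    dom = stage_domains(cfg, pairs, cctcf_ivs, domain_set)

    stage_counts = {
        "total_unique_sites": len(occ.entries),
        "cctcf": len(cctcf),
        "crad21": len(crad21),
        "csmc3": len(csmc3),
        "min_required_count": need,
        **constitutive.class_counts(labels),
    }
    result = PipelineResult(
        config=cfg, genome=genome, truth=truth, occurrence=occ, cctcf=cctcf,
        crad21=crad21, csmc3=csmc3, class_labels=labels, enrichment=enrich,
        type_counts=types, domain_summary=dom, conservation_summary=cons,
        composites=composites, stage_counts=stage_counts,
    )
    target = outdir or cfg.output_dir
    if target:
        _write_artifacts(result, Path(target))
    return result


def _write_artifacts(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    occ_path = outdir / "occurrence_table.tsv"
    res.occurrence.write_tsv(occ_path)
    cctcf_path = outdir / "cctcf_sites.bed"
    ivs = []
    for ident in sorted(res.cctcf):
        chrom, start, end, strand = ident
        ivs.append(GenomicInterval(chrom, start, end, strand,
                                   (res.class_labels.get(ident, "cCTCF"), "0")))
    write_bed(ivs, cctcf_path)
    res.type_counts.write_tsv(outdir / "interaction_types.tsv")
    for side, comp in res.composites.items():
        comp.write_pfm(outdir / f"composite_{side}.pfm")
    summary = {
        "stage_counts": res.stage_counts,
        "enrichment": res.enrichment,
        "domains": {
            "fraction_both_in_domains":
                res.domain_summary["interactions"]["fraction_both_in_domains"],
            "fraction_same_domain":
                res.domain_summary["interactions"]["fraction_same_domain"],
            "fraction_sites_in_domains": res.domain_summary["fraction_sites_in_domains"],
            "kde_mode": res.domain_summary["kde"]["mode"] if res.domain_summary["kde"] else None,
        },
        "conservation": {
            cls: {k: v for k, v in s.items() if k != "counts"}
            for cls, s in res.conservation_summary.items()
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    params = dataclasses.asdict(res.config)
    _write_manifest(outdir, "all", params,
                    [occ_path, cctcf_path, outdir / "interaction_types.tsv",
                     outdir / "summary.json"])
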