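"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the real inputs end to end: a random genome, a
constitutive core of CTCF motif instances shared (minus dropout) across
all cell lines plus cell-specific and mid-frequency instances, cohesin
peaks co-localizing with a tunable subset of the constitutive sites,
full-spectrum flank words implanted per class, ChIA-PET-like anchor
pairs realizing a target constitutive-site odds ratio, topological
domains with realistic length statistics, and per-species alignment
blocks with class-dependent motif retention.  Every stage of the
pipeline can therefore be scored against exact ground truth.

Defaults mirror the real survey: 56 CTCF cell lines (6 Rad21, 4 Smc3),
a >90% constitutive rule, a 0.60-vs-0.16 in-interaction split (odds
ratio 7.7), 680/852 kb median/mean domain lengths, a 0.8 same-domain
fraction, and 46 alignment species retained at 20/46 vs 10/46.
All randomness flows from one integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chiapet import InteractionPair
from .domains import DomainSet, TopologicalDomain
from .intervals import GenomicInterval, Peak, PointIndex
from .conservation import AlignmentBlock
from .pwm import BASES, PWMModel, encode, exact_pvalue_table, reverse_complement

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "ctcf_pwm",
    "generate_genome",
    "generate_peak_sets",
    "generate_domains",
    "generate_interactions",
    "generate_alignments",
    "plant_motif_array",
    "write_fasta",
    "load_fasta",
    "FLANK_LEFT_WORD",
    "FLANK_RIGHT_WORD",
]

# Flank words implanted adjacent to the 16-bp core.  The left 18-mer plus
# the core gives a 34-bp extended motif; the right word is a GAGA-like
# repeat whose recovery the k-mer machinery is tested against.
FLANK_LEFT_WORD = "TGCAGTGGTGGAGCAGGA"
FLANK_RIGHT_WORD = "GGAGGAGGAGG"

# 16-bp CTCF-core-like count matrix (columns A C G T), informative but
# degenerate at several positions as real motifs are.
_CTCF_COUNTS = [
    [8, 80, 6, 6],
    [5, 85, 5, 5],
    [70, 10, 12, 8],
    [8, 60, 25, 7],
    [5, 80, 8, 7],
    [75, 8, 9, 8],
    [4, 3, 90, 3],
    [30, 5, 60, 5],
    [4, 3, 40, 53],
    [4, 3, 90, 3],
    [5, 4, 85, 6],
    [8, 80, 5, 7],
    [30, 8, 55, 7],
    [10, 70, 12, 8],
    [8, 25, 7, 60],
    [50, 8, 35, 7],
]


def ctcf_pwm(pseudocount: float = 0.001) -> PWMModel:
    """The consensus-derived 16-bp core PWM shipped for tests and examples."""
    return PWMModel.from_counts(np.array(_CTCF_COUNTS, dtype=float), pseudocount=pseudocount)


@dataclass
class GeneratorConfig:
    """Knobs of the stated synthetic world; defaults are the survey's values."""

    seed: int = 0
    # survey geometry
    n_cell_lines: int = 56
    n_rad21_lines: int = 6
    n_smc3_lines: int = 4
    chrom_lengths: dict = field(
        default_factory=lambda: {f"chr{i}": 3_000_000 for i in range(1, 5)}
    )
    # site structure
    n_constitutive_sites: int = 500
    n_specific_sites_per_line: int = 20
    n_midfreq_sites: int = 200  # sites in 2-10 lines (conservation comparator frame)
    dropout_rate: float = 0.02
    cohesin_dropout_rate: float = 0.0
    peak_length: int = 200
    peak_jitter: int = 10
    core_implant_prob_constitutive: float = 1.0
    core_implant_prob_specific: float = 0.9
    # Implanted instances must out-score any background window in their peak,
    # or ground-truth site identity is ill-defined; at this margin the chance
    # of a stronger background window within a peak is < 0.1% per site.
    implant_score_margin: float = 5.5
    pvalue_cutoff: float = 0.0005
    # cohesin co-localization (fractions of constitutive sites)
    cohesin_full_fraction: float = 0.5
    cohesin_none_fraction: float = 0.05
    # full-spectrum flank implant probabilities per class
    flank_left_probs: dict = field(
        default_factory=lambda: {
            "cCTCF_cCohesin": 0.148, "cCTCF_non_cohesin": 0.038, "other": 0.018,
        }
    )
    flank_right_probs: dict = field(
        default_factory=lambda: {
            "cCTCF_cCohesin": 0.082, "cCTCF_non_cohesin": 0.037, "other": 0.012,
        }
    )
    # interactions
    n_interaction_pairs: int = 5000
    target_odds_ratio: float = 7.7
    nonconst_in_interaction_prob: float = 0.16
    anchor_width: int = 2000
    neither_anchor_fraction: float = 0.15
    same_domain_fraction: float = 0.8
    outside_pair_fraction: float = 0.05
    # domains
    domain_median_length: int = 680_000
    domain_mean_length: int = 852_000
    domain_gap_range: tuple = (20_000, 60_000)
    domain_min_length: int = 120_000
    # alignments
    n_species: int = 46
    retention_prob_constitutive: float = 20 / 46
    retention_prob_nonconstitutive: float = 10 / 46
    alignment_flank: int = 10
    flank_mutation_rate: float = 0.1
    block_split_prob: float = 0.0

    def cell_lines(self) -> list[str]:
        return [f"CL{i:02d}" for i in range(1, self.n_cell_lines + 1)]

    def rad21_lines(self) -> list[str]:
        return self.cell_lines()[: self.n_rad21_lines]

    def smc3_lines(self) -> list[str]:
        return self.cell_lines()[: self.n_smc3_lines]


@dataclass
class SyntheticTruth:
    """Ground-truth labels emitted alongside every generated object."""

    constitutive_sites: list[GenomicInterval] = field(default_factory=list)
    specific_sites: dict = field(default_factory=dict)  # line -> [GenomicInterval]
    midfreq_sites: list[GenomicInterval] = field(default_factory=list)
    cohesin_class: dict = field(default_factory=dict)  # identity -> class label
    flank_left_sites: set = field(default_factory=set)
    flank_right_sites: set = field(default_factory=set)
    in_interaction_const: set = field(default_factory=set)
    in_interaction_nonconst: set = field(default_factory=set)
    pair_same_domain: list = field(default_factory=list)  # bool per generated pair

    def all_nonconstitutive_sites(self) -> list[GenomicInterval]:
        out = [s for sites in self.specific_sites.values() for s in sites]
        out.extend(self.midfreq_sites)
        return out


def generate_genome(config: GeneratorConfig, rng: np.random.Generator | None = None) -> dict:
    """I.i.d. uniform-base chromosomes as {chrom: str}."""
    rng = rng or np.random.default_rng(config.seed)
    genome = {}
    for chrom, length in config.chrom_lengths.items():
        if length < 10_000:
            raise ValueError(f"{chrom}: chromosome shorter than 10 kb")
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        genome[chrom] = "".join(BASES[c] for c in codes) if length < 64 else _codes_to_str(codes)
    return genome


def _codes_to_str(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def _sample_passing_instance(
    pwm: PWMModel, rng: np.random.Generator, min_score: float, tries: int = 60
) -> str:
    """Draw a motif instance from the PWM conditional on a passing score.

    Bound sites are, by construction, sequences the scanner recognizes;
    sampling is rejected until the instance clears the call threshold
    (falls back to the consensus, which always does for this matrix).
    """
    lom = pwm.log_odds()
    idx = np.arange(pwm.width)
    for _ in range(tries):
        codes = np.array(
            [rng.choice(4, p=pwm.probs[i]) for i in range(pwm.width)], dtype=np.int64
        )
        if float(lom[idx, codes].sum()) >= min_score:
            return "".join(BASES[c] for c in codes)
    return pwm.consensus()


def _choose_site_positions(
    config: GeneratorConfig, n_needed: int, rng: np.random.Generator, width: int
) -> list[tuple[str, int]]:
    """Widely spaced (chrom, start) positions on a slot grid.

    Slots are 4 kb apart with sites confined to a narrow central band, so
    any two sites are farther apart than an interaction anchor can reach:
    a peak or anchor placed over one site never touches another.
    """
    slot = 4000
    band = 150  # site start varies within slot_center +- band/2
    edge = 300  # keep clear of contig ends (peaks, flank extraction)
    slots: list[tuple[str, int]] = []
    for chrom, length in config.chrom_lengths.items():
        for s in range(edge, length - slot - edge, slot):
            slots.append((chrom, s))
    if n_needed > len(slots):
        raise ValueError(
            f"genome too small: {n_needed} sites requested, {len(slots)} slots available"
        )
    chosen = rng.choice(len(slots), size=n_needed, replace=False)
    out = []
    for i in chosen:
        chrom, s = slots[int(i)]
        center = s + slot // 2
        out.append((chrom, center - width // 2 + int(rng.integers(-band // 2, band // 2 + 1))))
    return out


def _implant(genome_arrays: dict, site: GenomicInterval, core: str,
             left_word: str | None, right_word: str | None) -> None:
    """Write core (+ optional flank words) into the genome at the site.

    The conceptual plus-orientation string is left|core|right; for a
    minus-strand site its reverse complement is written so the motif
    reads on the minus strand, with the core still at [start, end).
    """
    left = left_word or ""
    right = right_word or ""
    conceptual = left + core + right
    if site.strand == "-":
        lo = site.start - len(right)
        payload = reverse_complement(conceptual)
    else:
        lo = site.start - len(left)
        payload = conceptual
    arr = genome_arrays[site.chrom]
    arr[lo : lo + len(payload)] = payload.encode("ascii")


def generate_peak_sets(
    config: GeneratorConfig,
    genome: dict,
    pwm: PWMModel | None = None,
    rng: np.random.Generator | None = None,
):
    """Per-cell-line CTCF peaks, cohesin peaks, implanted genome, truth.

    Returns (ctcf_peaks_by_line, cohesin_peaks, genome_with_implants,
    truth) where ``cohesin_peaks`` maps protein -> cell line -> [Peak].
    Constitutive motif instances are implanted once into the genome and
    covered by a (jittered) peak in each cell line with probability
    1 - dropout; cell-specific instances get a peak in exactly one line;
    mid-frequency instances in 2-10 lines.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    pwm = pwm or ctcf_pwm()
    width = pwm.width
    table = exact_pvalue_table(pwm)
    min_score = table.score_threshold(config.pvalue_cutoff) + config.implant_score_margin

    lines = config.cell_lines()
    n_specific = config.n_specific_sites_per_line * len(lines)
    n_total = config.n_constitutive_sites + n_specific + config.n_midfreq_sites
    positions = _choose_site_positions(config, n_total, rng, width)
    genome_arrays = {c: bytearray(s, "ascii") for c, s in genome.items()}

    truth = SyntheticTruth(specific_sites={ln: [] for ln in lines})
    half = config.peak_length // 2

    def make_site(pos_i: int) -> GenomicInterval:
        chrom, start = positions[pos_i]
        strand = "+" if rng.random() < 0.5 else "-"
        return GenomicInterval(chrom, start, start + width, strand)

    def make_peak(site: GenomicInterval, line: str, dataset: str) -> Peak:
        center = site.midpoint + int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
        iv = GenomicInterval(site.chrom, center - half, center - half + config.peak_length)
        return Peak(iv, source_cell_line=line, source_dataset=dataset)

    # --- constitutive sites -------------------------------------------------
    pos_i = 0
    classes = _assign_cohesin_classes(config, rng)
    for k in range(config.n_constitutive_sites):
        site = make_site(pos_i)
        pos_i += 1
        cls = classes[k]
        truth.constitutive_sites.append(site)
        truth.cohesin_class[site.identity()] = cls
        lw = rw = None
        if rng.random() < config.flank_left_probs.get(cls, config.flank_left_probs["other"]):
            lw = FLANK_LEFT_WORD
            truth.flank_left_sites.add(site.identity())
        if rng.random() < config.flank_right_probs.get(cls, config.flank_right_probs["other"]):
            rw = FLANK_RIGHT_WORD
            truth.flank_right_sites.add(site.identity())
        if rng.random() < config.core_implant_prob_constitutive:
            core = _sample_passing_instance(pwm, rng, min_score)
            _implant(genome_arrays, site, core, lw, rw)

    # --- cell-specific sites ------------------------------------------------
    for line in lines:
        for _ in range(config.n_specific_sites_per_line):
            site = make_site(pos_i)
            pos_i += 1
            truth.specific_sites[line].append(site)
            if rng.random() < config.core_implant_prob_specific:
                core = _sample_passing_instance(pwm, rng, min_score)
                _implant(genome_arrays, site, core, None, None)

    # --- mid-frequency sites (2-10 lines) ------------------------------------
    midfreq_lines: list[list[str]] = []
    for _ in range(config.n_midfreq_sites):
        site = make_site(pos_i)
        pos_i += 1
        truth.midfreq_sites.append(site)
        k = int(rng.integers(2, 11))
        members = [lines[int(j)] for j in rng.choice(len(lines), size=k, replace=False)]
        midfreq_lines.append(members)
        if rng.random() < config.core_implant_prob_specific:
            core = _sample_passing_instance(pwm, rng, min_score)
            _implant(genome_arrays, site, core, None, None)

    genome_implanted = {c: a.decode("ascii") for c, a in genome_arrays.items()}

    # --- peaks ----------------------------------------------------------------
    peaks_by_line: dict[str, list[Peak]] = {ln: [] for ln in lines}
    for site in truth.constitutive_sites:
        for line in lines:
            if rng.random() >= config.dropout_rate:
                peaks_by_line[line].append(make_peak(site, line, "synthCTCF"))
    for line, sites in truth.specific_sites.items():
        for site in sites:
            peaks_by_line[line].append(make_peak(site, line, "synthCTCF"))
    for site, members in zip(truth.midfreq_sites, midfreq_lines):
        for line in members:
            peaks_by_line[line].append(make_peak(site, line, "synthCTCF"))

    cohesin_peaks = _make_cohesin_peaks(config, truth, rng, make_peak)
    return peaks_by_line, cohesin_peaks, genome_implanted, truth


def _assign_cohesin_classes(config: GeneratorConfig, rng: np.random.Generator) -> list[str]:
    n = config.n_constitutive_sites
    labels = []
    for _ in range(n):
        r = rng.random()
        if r < config.cohesin_full_fraction:
            labels.append("cCTCF_cCohesin")
        elif r < config.cohesin_full_fraction + config.cohesin_none_fraction:
            labels.append("cCTCF_non_cohesin")
        else:
            labels.append("other")
    return labels


def _make_cohesin_peaks(config, truth: SyntheticTruth, rng, make_peak):
    """Rad21/Smc3 peaks over constitutive sites according to their class."""
    rad_lines, smc_lines = config.rad21_lines(), config.smc3_lines()
    cohesin = {
        "Rad21": {ln: [] for ln in rad_lines},
        "Smc3": {ln: [] for ln in smc_lines},
    }
    for site in truth.constitutive_sites:
        cls = truth.cohesin_class[site.identity()]
        if cls == "cCTCF_cCohesin":
            use_rad, use_smc = rad_lines, smc_lines
        elif cls == "cCTCF_non_cohesin":
            continue
        else:
            # partial support: some cohesin lines but never the full set of both
            n_r = int(rng.integers(0, len(rad_lines)))  # 0..5 of 6
            n_s = int(rng.integers(0, len(smc_lines)))  # 0..3 of 4
            if n_r == 0 and n_s == 0:
                n_r = 1
            use_rad = [rad_lines[int(i)] for i in rng.choice(len(rad_lines), n_r, replace=False)]
            use_smc = [smc_lines[int(i)] for i in rng.choice(len(smc_lines), n_s, replace=False)]
        for ln in use_rad:
            if rng.random() >= config.cohesin_dropout_rate:
                cohesin["Rad21"][ln].append(make_peak(site, ln, "synthRad21"))
        for ln in use_smc:
            if rng.random() >= config.cohesin_dropout_rate:
                cohesin["Smc3"][ln].append(make_peak(site, ln, "synthSmc3"))
    return cohesin


def generate_domains(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> DomainSet:
    """Non-overlapping domains tiling each chromosome with small gaps.

    Lengths are lognormal with the configured median and mean (sigma
    follows from their ratio), so most of the genome is inside domains.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    mu = math.log(config.domain_median_length)
    ratio = config.domain_mean_length / config.domain_median_length
    sigma = math.sqrt(max(2 * math.log(ratio), 1e-9))
    domains = []
    for chrom, length in config.chrom_lengths.items():
        pos = int(rng.integers(*config.domain_gap_range))
        while True:
            dlen = int(rng.lognormal(mu, sigma))
            dlen = max(config.domain_min_length, min(dlen, length // 2))
            if pos + dlen > length - 1000:
                # fill the chromosome tail so nearly all sites fall in domains
                if length - 1000 - pos >= config.domain_min_length:
                    domains.append(
                        TopologicalDomain(GenomicInterval(chrom, pos, length - 1000))
                    )
                break
            domains.append(TopologicalDomain(GenomicInterval(chrom, pos, pos + dlen)))
            pos += dlen + int(rng.integers(*config.domain_gap_range))
    return DomainSet(domains)


def _odds_to_prob(odds: float) -> float:
    return odds / (1 + odds)


def generate_interactions(
    config: GeneratorConfig,
    truth: SyntheticTruth,
    domains: DomainSet,
    rng: np.random.Generator | None = None,
) -> list[InteractionPair]:
    """Anchor pairs realizing the target constitutive-site odds ratio.

    Each constitutive site joins the in-interaction set with probability
    p1 and each non-constitutive site with probability p0, where
    odds(p1)/odds(p0) equals the target odds ratio (p0 is the configured
    non-constitutive in-interaction proportion).  Every selected site
    receives a 2-kb anchor; anchors are then paired with the configured
    same-domain preference.  Selections are recorded in the truth object.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    p0 = config.nonconst_in_interaction_prob
    odds1 = config.target_odds_ratio * p0 / (1 - p0)
    p1 = _odds_to_prob(odds1)
    n1 = len(truth.constitutive_sites)
    # need a few sites on both margins or the realized odds ratio saturates
    if not 0 < p1 < 1 or n1 * (1 - p1) < 5 or n1 * p1 < 5:
        odds0 = p0 / (1 - p0)
        hi = ((1 - 5 / n1) / (5 / n1)) / odds0 if n1 > 5 else 0.0
        lo = ((5 / n1) / (1 - 5 / n1)) / odds0 if n1 > 5 else 0.0
        raise ValueError(
            f"target odds ratio {config.target_odds_ratio} infeasible with "
            f"baseline proportion {p0} and {n1} constitutive sites; "
            f"feasible range is about [{lo:.3g}, {hi:.3g}]"
        )

    anchors: list[GenomicInterval] = []
    half = config.anchor_width // 2
    jitter = max(half - 100, 1)

    def add_anchor(center_chrom: str, center: int) -> None:
        c = center + int(rng.integers(-jitter, jitter + 1))
        anchors.append(GenomicInterval(center_chrom, max(0, c - half), max(0, c - half) + config.anchor_width))

    for site in truth.constitutive_sites:
        if rng.random() < p1:
            truth.in_interaction_const.add(site.identity())
            add_anchor(site.chrom, site.midpoint)
    for site in truth.all_nonconstitutive_sites():
        if rng.random() < p0:
            truth.in_interaction_nonconst.add(site.identity())
            add_anchor(site.chrom, site.midpoint)

    # anchors covering no site at all
    site_points = PointIndex(
        (s.chrom, s.midpoint)
        for s in truth.constitutive_sites + truth.all_nonconstitutive_sites()
    )
    n_neither = int(config.neither_anchor_fraction * len(anchors))
    chroms = list(config.chrom_lengths)
    made = 0
    while made < n_neither:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(half, config.chrom_lengths[chrom] - half))
        if not site_points.any_within(chrom, pos, half + 200):
            anchors.append(GenomicInterval(chrom, pos - half, pos + half))
            made += 1

    if len(anchors) < 4:
        raise ValueError("too few anchors to form interaction pairs")

    # Group in-domain anchors by (chrom, domain).  Pairing branches:
    #   outside      (prob q)       — one anchor outside any domain; the pair
    #                                 drops out of the same-domain denominator;
    #   same-domain  (prob (1-q)f)  — two anchors in one domain;
    #   cross-domain (else)         — two anchors in different domains on the
    #                                 same chromosome.
    # Same- and cross-domain pairs both count in the measured same-domain
    # denominator, so the recovered fraction equals f in expectation.
    in_domain: dict[str, dict[int, list[int]]] = {}
    outside: list[int] = []
    for i, a in enumerate(anchors):
        dom = domains.containing(a.chrom, a.midpoint)
        if dom is None:
            outside.append(i)
        else:
            in_domain.setdefault(a.chrom, {}).setdefault(id(dom), []).append(i)
    multi = [
        (chrom, key)
        for chrom, doms in in_domain.items()
        for key, members in doms.items()
        if len(members) >= 2
    ]
    cross_chroms = [c for c, doms in in_domain.items() if len(doms) >= 2]
    if not multi or not cross_chroms:
        raise ValueError("domain structure too sparse for same/cross-domain pairing")
    multi_w = np.array([len(in_domain[c][k]) for c, k in multi], dtype=float)
    multi_w /= multi_w.sum()
    all_in_domain = [i for doms in in_domain.values() for m in doms.values() for i in m]

    q = config.outside_pair_fraction if outside else 0.0
    f = config.same_domain_fraction
    pairs: list[InteractionPair] = []
    for pid in range(config.n_interaction_pairs):
        r = rng.random()
        if r < q:
            i = outside[int(rng.integers(len(outside)))]
            j = all_in_domain[int(rng.integers(len(all_in_domain)))]
            a1, a2, same = anchors[i], anchors[j], False
        elif r < q + (1 - q) * f:
            chrom, key = multi[int(rng.choice(len(multi), p=multi_w))]
            members = in_domain[chrom][key]
            i, j = rng.choice(len(members), size=2, replace=False)
            a1, a2, same = anchors[members[int(i)]], anchors[members[int(j)]], True
        else:
            chrom = cross_chroms[int(rng.integers(len(cross_chroms)))]
            dkeys = list(in_domain[chrom])
            ki, kj = rng.choice(len(dkeys), size=2, replace=False)
            m1 = in_domain[chrom][dkeys[int(ki)]]
            m2 = in_domain[chrom][dkeys[int(kj)]]
            a1 = anchors[m1[int(rng.integers(len(m1)))]]
            a2 = anchors[m2[int(rng.integers(len(m2)))]]
            same = False
        truth.pair_same_domain.append(same)
        pairs.append(InteractionPair(a1, a2, f"pair{pid}"))
    return pairs


def write_fasta(genome: dict, path) -> None:
    """Write {chrom: sequence} as wrapped FASTA."""
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def load_fasta(path) -> dict:
    """Read a FASTA into {chrom: sequence} (indexed access via pyfaidx)."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def plant_motif_array(
    config: GeneratorConfig,
    n_sites: int,
    pwm: PWMModel | None = None,
    rng: np.random.Generator | None = None,
    spacing: int = 60,
) -> tuple[dict, list[GenomicInterval]]:
    """A single contig with ``n_sites`` implanted motif instances in a row.

    A lightweight alternative to the full peak generator for analyses that
    only need motif-bearing loci (e.g. alignment/conservation studies).
    Returns ({chrom: seq}, sites); sites are spaced so their flanking
    windows never overlap.
    """
    rng = rng or np.random.default_rng(config.seed + 5)
    pwm = pwm or ctcf_pwm()
    w = pwm.width
    if spacing < w + 2 * config.alignment_flank + 4:
        raise ValueError("spacing too small for non-overlapping alignment windows")
    table = exact_pvalue_table(pwm)
    min_score = table.score_threshold(config.pvalue_cutoff) + config.implant_score_margin
    length = 200 + n_sites * spacing
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    arr = bytearray(_codes_to_str(codes), "ascii")
    sites = []
    for i in range(n_sites):
        start = 100 + i * spacing
        strand = "+" if rng.random() < 0.5 else "-"
        inst = _sample_passing_instance(pwm, rng, min_score)
        payload = inst if strand == "+" else reverse_complement(inst)
        arr[start : start + w] = payload.encode("ascii")
        sites.append(GenomicInterval("chrA", start, start + w, strand))
    return {"chrA": arr.decode("ascii")}, sites


def generate_alignments(
    config: GeneratorConfig,
    sites: Sequence[GenomicInterval],
    genome: dict,
    retention_prob: float,
    rng: np.random.Generator | None = None,
) -> list[AlignmentBlock]:
    """One alignment block per site: 16-bp core plus flanks, 46 species.

    The reference row is the (implanted) genome slice.  Each non-reference
    species retains the motif with ``retention_prob`` — its core matches
    the reference while flank bases mutate at the configured rate — or
    loses it, in which case the core is randomized.  With
    ``block_split_prob`` a block is emitted as two consecutive blocks to
    exercise merging.
    """
    rng = rng or np.random.default_rng(config.seed + 4)
    fl = config.alignment_flank
    species = ["hg19"] + [f"sp{i:02d}" for i in range(1, config.n_species)]
    blocks: list[AlignmentBlock] = []
    for idx, site in enumerate(sites):
        lo, hi = site.start - fl, site.end + fl
        ref = genome[site.chrom][lo:hi]
        L = len(ref)
        core_lo, core_hi = fl, fl + site.length
        rows = {"hg19": ref}
        for sp in species[1:]:
            chars = list(ref)
            for i in list(range(0, core_lo)) + list(range(core_hi, L)):
                if rng.random() < config.flank_mutation_rate:
                    chars[i] = BASES[int(rng.integers(4))]
            if rng.random() >= retention_prob:  # motif lost
                for i in range(core_lo, core_hi):
                    chars[i] = BASES[int(rng.integers(4))]
            rows[sp] = "".join(chars)
        block = AlignmentBlock(
            GenomicInterval(site.chrom, lo, hi, "+"), "hg19", rows, index=idx
        )
        if rng.random() < config.block_split_prob and L > 4:
            cut = int(rng.integers(2, L - 2))
            left = AlignmentBlock(
                GenomicInterval(site.chrom, lo, lo + cut, "+"),
                "hg19",
                {sp: seq[:cut] for sp, seq in rows.items()},
                index=idx,
            )
            right = AlignmentBlock(
                GenomicInterval(site.chrom, lo + cut, hi, "+"),
                "hg19",
                {sp: seq[cut:] for sp, seq in rows.items()},
                index=idx,
            )
            blocks.extend([left, right])
        else:
            blocks.append(block)
    return blocks
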