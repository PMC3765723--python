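# Methods

This note records the models, defaults, numerical choices, and limitations
behind `consites`. Everything quantitative stated here is computed by the
test suite or the examples; nothing is asserted that the code does not
measure.

## Coordinates and peaks

All coordinates are 0-based half-open (BED convention). The midpoint of an
interval is `start + length // 2` (floor for odd lengths) — deterministic and
consistent with common peak-caller output. Peaks are extended/trimmed to a
fixed length (default 200 bp) around the midpoint; the window is clipped at
position 0 (the result may then be shorter), and no clipping is applied at
chromosome ends, since chromosome sizes are optional. Clipping makes
re-normalization of a clipped peak non-idempotent; idempotence holds
everywhere else and is property-tested in that regime. ENCODE narrowPeak
summit offsets are carried on the `Peak` type but unused: centering follows
the peak midpoint, matching the "center of the peak" convention.

## PWM scoring and exact p-values

Scores are log-odds with a pseudocount (default 0.001) added inside both
logarithms, so zero matrix entries stay finite; the background defaults to
uniform 0.25 and is configurable. Windows containing N score −∞ rather than
being averaged — conservative, and it prevents spurious calls in masked
sequence.

P-values are exact tail probabilities of the score under the background,
computed by discretizing each position's four possible scores to a lattice
(granularity 10⁻³ log-odds units) and convolving the per-position
distributions. Each position rounds independently, so a computed score and
its lattice value can differ by at most `width × granularity / 2`; the test
suite checks the table against full 4^w enumeration for widths ≤ 8 inside
exactly that envelope. At the extreme upper tail the lattice can round a
score just past the last occupied bin, reporting p = 0 instead of ~10⁻¹⁰;
irrelevant at any practical cutoff.

Site calling selects the single highest-scoring window over both strands and
all offsets; since the p-value is monotone in the score, this window passes
the cutoff iff any window does. Ties break leftmost, then '+'. The site's
strand is the scan strand of the winning window.

The CTCF core PWM itself is an input. A consensus-derived 16-bp
CTCF-core-like matrix ships with the package for tests and examples; it is
informative (~16.5 bits max log-odds) with degenerate positions, as real
motifs are, but it is not the laboratory matrix, which users should supply
as a plain-text counts/probabilities file.

## Constitutive calling and cohesin classes

Site identity across cell lines is exact (chrom, start, end, strand)
equality: best PWM hits in peaks covering the same genomic motif instance
land on identical coordinates, which is what makes coordinate-level identity
sound. An optional fuzzy mode (single-linkage clustering within ± tolerance
bp, default off) is available for noisy real data.

The constitutive rule is strict: count / N must *exceed* the fraction
(0.9), so 9 of 10 lines does not qualify while 51 of 56, 6 of 6, and 4 of 4
do. Constitutive status for Rad21/Smc3 is evaluated on the CTCF-motif hits
inside those proteins' peaks, with each protein's own cell-line count.
`cCTCF/cCohesin` is the identity-level intersection of the three
constitutive sets; `cCTCF-non-cohesin` requires zero interval overlap with
any cohesin peak in any cell line (site-vs-peak overlap, not identity, since
absence must be tested against the raw peaks). Everything else is partial
support, deliberately left unclassified as either extreme.

## Genomic context

A site's category is decided by its midpoint with first-match-wins ordering:
within ±5 kb of any TSS → "TSS", else inside any gene span → "in gene", else
"others"; a site near one gene's TSS but inside another gene is "TSS". The
feature-density profile reports, for each offset o in ±2.5 kb, the fraction
of sites whose (center + o) base lies in ≥ 1 feature interval — a coverage
profile, unsmoothed. Co-factor overlap asks whether a factor's peak *center*
falls within ±200 bp of the site center, evaluated per (factor, cell line);
an empty site class reports missing rather than 0.

## Full-spectrum motifs

Sites are extended 30 bp per side (76 bp, minus-strand sites
reverse-complemented so the core reads forward). Presence of each 5-mer is
counted per start position (0/1 per sequence; 72 positions × 1,024 words).
Side assignment is by the word's start offset: left = 0..29, right = 46..71;
words starting inside the core belong to neither side — a deterministic
partition of the 72 windows. Words are ranked by their *maximum
single-position* count within the side rather than the positional sum:
positional specificity is what separates motif words from composition bias
(the statistic is configurable). The top 50 words per side deposit their
positional counts onto the bases they spell; columns normalize to 1, and
zero-support columns become uniform with a warning. The left composite spans
offsets 0..33 (34 columns, reaching into the core) and the right spans
46..75 (30 columns); a trimming utility drops weakly supported edge columns
so one composite can be reported at more than one width — the package emits
the trimmed variants rather than deciding whether a flank pattern is one
motif or two. Prevalence of a motif in a site class is the fraction of
extended sequences whose *anchored* window (composites know their offsets; a
bare core PWM anchors at the core) reaches the exact-p-value cutoff,
forward strand only since the sequences are core-oriented.

## Conservation

Alignment blocks cover the site ± 10 bp. Blocks split by an extraction tool
are merged by concatenation in reference order (absent species gap-filled;
overlapping blocks are an error). Each species' row is gap-stripped and
scanned on both strands with the same PWM and cutoff; the conservation
statistic is the count of species with ≥ 1 passing window, reference
included. A hit anywhere in the ~36-bp span counts — no requirement that it
align to the original site position. Species with rows shorter than the PWM
width after gap removal (including wholly missing species) count as absent.
No phylogenetic model is used; the species count is the only statistic.

## Interactions

"Site in interaction" means any interval overlap between the 16-bp site and
any region of any pair; a site counts once regardless of multiplicity.
Enrichment reports the sample (cross-product) odds ratio — infinite with a
warning when a denominator cell is zero — and a one-sided Fisher exact
p-value (scipy's exact hypergeometric tail; the test suite proves it against
an independent `math.comb` summation). Fractional typing labels each region
with the *set* of distinct site classes it contains ({cCTCF}, {nonconst},
both, or {neither}) and splits the pair's unit weight uniformly over the
Cartesian product of the two label sets — uniform over label combinations,
not proportional to site multiplicities, following the one worked convention
available. Label sets have at most two elements, so all weights are 1, 1/2,
or 1/4 — exact in binary floating point — and totals equal the pair count
exactly, which is asserted, not approximated. Replicate interaction
experiments are analyzed separately.

## Domains

Sites and regions are assigned to the domain containing their midpoint
(half-open intervals, so a point on a start boundary belongs to the domain
starting there). Boundary distance is from the midpoint to the nearer
boundary, standardized as `raw × median_length / domain_length` — i.e.
distances as if every domain had the median length, the only reading of
"standardized to the median length" that makes densities comparable across
domain sizes (simple truncation would not). Same-domain fractions are
computed over intra-chromosomal pairs with both regions inside domains. The
KDE is Gaussian with Silverman's bandwidth, evaluated on [0, max] with
reflection at zero so no mass is lost below the origin; degenerate all-equal
input returns a point mass with a warning.

## Synthetic data: what it emulates, and what it does not

The generator states a world mirroring the published survey: 56 CTCF cell
lines (6 Rad21, 4 Smc3), 2% per-line peak dropout, 200-bp peaks with ±10 bp
center jitter, a 0.60-vs-0.16 in-interaction split (odds ratio 7.7 via the
odds transform), 2-kb interaction anchors, 0.8 same-domain fraction,
lognormal domain lengths with 680/852 kb median/mean and 20–60 kb boundary
gaps, and 46 alignment species with 20/46 vs 10/46 motif retention. Counts
are scaled down (500 constitutive sites, 20 cell-specific per line, 200
mid-frequency sites on a 12-Mb genome) so the full pipeline runs in seconds;
the statistical structure, not the genome size, is what the analyses test.

Design choices that matter:

- **Site spacing.** Sites sit on a 4-kb slot grid, farther apart than a peak
  or 2-kb anchor can reach, so an anchor placed over one site never covers a
  neighbor. Without this, anchor spillover would contaminate the planted
  odds ratio.
- **Implant strength.** Motif instances are drawn from the PWM conditional
  on scoring ≥ threshold + 5.5 log-odds. A planted "bound site" must
  out-score every background window in its peak or its ground-truth
  coordinates are ill-defined (a fixed stronger background window would hijack
  the best-site call in *every* cell line); at this margin the chance of
  such a window is < 0.1% per site, while ~40% of unconditioned PWM draws
  still pass. Constitutive sites always carry an implant; cell-specific
  sites carry one with probability 0.9, landing the per-peak call rate in
  the realistic 80–95% band once background false positives (~17% per
  motif-free 200-bp peak at the 5 × 10⁻⁴ cutoff) are included.
- **Pairing branches.** Interaction pairs are drawn same-domain with the
  configured probability f, otherwise cross-domain on the same chromosome,
  with a small fraction involving an out-of-domain anchor; same- and
  cross-domain branches both land in the measured same-domain denominator,
  so the recovered fraction equals f in expectation rather than being
  inflated by denominator exclusions.
- **Alignments** contain substitutions (10% per flank base) but no gaps;
  gap handling is exercised by merge-fill and hand-built gapped blocks in
  the tests instead. Non-retained species randomize the core, so they still
  hit by chance with probability ≈ 1 − (1 − α)^42 ≈ 2% (α the per-window
  tail at the cutoff); retention estimators should subtract this floor, as
  the tests do.

What a green test does **not** establish: real ChIP-seq peaks overlap and
drift across datasets (the fuzzy identity mode exists for that, but the
default world does not exercise it); real backgrounds are not i.i.d. uniform
(no CpG composition, repeats, or mappability artifacts); real constitutive
sites are not all strong motif matches; and real boundary-distance
distributions are not uniform — the boundary-enrichment KDE mode is
therefore validated on explicitly peaked distance draws, not on the
pipeline's uniformly placed sites.

## Recovery guarantees and their arithmetic limits

With N = 56 lines, the strict >90% rule needs 51 appearances, tolerating at
most 5 dropouts. At the default 2% dropout, P(≥ 6 dropouts) ≈ 3 × 10⁻⁴ and
recovery of planted constitutive sites exceeds 99%. This bound is not
achievable at every dropout below 10%: at 5% dropout, P(≥ 6 of 56) ≈ 0.06,
capping recovery near 94% regardless of implementation. The ≥ 99% recovery
check is therefore meaningful only in the ≲ 3% dropout regime, where the
stated world sits. Similarly, the planted odds ratio is a Bernoulli-sampling
target: at 500/1,300 sites its realized value has a log-scale standard error
of ~0.12, so recovery is asserted against the Monte-Carlo confidence
interval, not as a point match.

## Pipeline

Stage functions take a single config whose defaults equal the published
thresholds (200 bp, 5 × 10⁻⁴, 0.9, ±5 kb, ±2.5 kb, ±200 bp, 30-bp flanks,
k = 5, top 50); invalid thresholds fail at construction, before any work.
Outputs are deterministic given (inputs, seed); each run writes a manifest
with parameters and SHA-256 checksums of its artifacts, and identical seeds
reproduce artifacts byte-for-byte. The package is driven from Python — the
stage functions and the `examples/` scripts are the operational interface.
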