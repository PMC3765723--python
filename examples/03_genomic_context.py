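"""Situate binding sites in their genomic context.

Classifies sites as TSS-proximal (+-5 kb), inside a gene body, or
intergenic; profiles feature coverage (e.g. CpG islands) around site
centers; and measures how often another factor's peak center falls
within +-200 bp of a site.
"""

import numpy as np

from consites import GenomicInterval, Peak, annotate_sites, factor_overlap_fraction, feature_density_profile
from consites.annotation import GeneModel

rng = np.random.default_rng(1)

genes = [GeneModel("geneA", GenomicInterval("chr1", 100_000, 180_000, "+"))]
sites = [
    GenomicInterval("chr1", 97_000, 97_016),   # 3 kb upstream of the TSS
    GenomicInterval("chr1", 150_000, 150_016), # deep in the gene body
    GenomicInterval("chr1", 800_000, 800_016), # intergenic
]
print("TSS / in-gene / others:", annotate_sites(sites, genes, tss_window=5000))

cpg = [GenomicInterval("chr1", 96_500, 98_200)]
prof = feature_density_profile(sites, cpg, halfwidth=2500)
print(f"CpG coverage at offset 0: {prof.values[2500]:.2f} "
      f"(1 of 3 sites sits in an island)")

dnase = [Peak(GenomicInterval("chr1", 96_950, 97_150)),
         Peak(GenomicInterval("chr1", 149_900, 150_100))]
frac = factor_overlap_fraction(sites, dnase, margin=200)
print(f"fraction of sites with a DNase peak center within +-200 bp: {frac:.2f}")
print("Two of the three sites are in open chromatin by this criterion.")
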