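"""Call the best CTCF site in a ChIP-seq peak with exact p-values.

Builds a random 200-bp peak, implants the 16-bp core motif consensus at
offset 60, and scans both strands.  The reported p-value is the exact
probability that a random background window scores at least as high.
"""

import numpy as np

from consites import GenomicInterval, Peak, best_site_in_peak, ctcf_pwm, exact_pvalue_table

rng = np.random.default_rng(0)
pwm = ctcf_pwm()
table = exact_pvalue_table(pwm)

background = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
peak_seq = background[:60] + pwm.consensus() + background[76:]
peak = Peak(GenomicInterval("chr1", 10_000, 10_200), source_cell_line="K562")

site = best_site_in_peak(pwm, peak_seq, peak, pvalue_cutoff=0.0005, table=table)
print(f"consensus implanted at peak offset 60 -> site called at "
      f"{site.interval.chrom}:{site.interval.start}-{site.interval.end} ({site.interval.strand})")
print(f"log-odds score {site.score:.2f}, exact p-value {site.pvalue:.2e}")
print("The site lands exactly on the implant; the tiny p-value says a random")
print("window essentially never reaches this score under the background model.")
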