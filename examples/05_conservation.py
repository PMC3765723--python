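"""Compare cross-species conservation of two site classes.

For each site, a 46-species alignment block over the site +-10 bp is
scanned per species with the same PWM and p-value cutoff used to call
the site; the number of species with a hit is the conservation score.
Constitutive-like sites retain the motif in each species with
probability 20/46, the comparator class with 10/46.
"""

import numpy as np

from consites import conservation_summary, ctcf_pwm, exact_pvalue_table, species_with_hit
from consites import synthetic as syn

pwm = ctcf_pwm()
table = exact_pvalue_table(pwm)
cfg = syn.GeneratorConfig(seed=4, n_species=46)
genome, sites = syn.plant_motif_array(cfg, 400, pwm)

counts = {}
for label, retention in (("constitutive", 20 / 46), ("non-constitutive", 10 / 46)):
    blocks = syn.generate_alignments(
        cfg, sites, genome, retention_prob=retention,
        rng=np.random.default_rng(int(retention * 1000)),
    )
    counts[label] = [species_with_hit(b, pwm, 0.0005, table) for b in blocks]

for label, summary in conservation_summary(counts).items():
    print(f"{label:17s} mean {summary['mean']:5.1f} species  "
          f"median {summary['median']:4.0f}  IQR [{summary['q1']:.0f}, {summary['q3']:.0f}]")
print("Constitutive-like sites are found in roughly twice as many species,")
print("mirroring their planted 20/46-vs-10/46 retention probabilities.")
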