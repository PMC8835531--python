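"""Generate a synthetic pool-seq experiment and scan it for
treatment-differentiated SNPs with the generalized CMH test.

The synthetic study mirrors a 3-treatment x 10-replicate evolve-and-
resequence design: the scan stratifies allele read counts by matched
replicate set, so Q is large only where allele frequencies differ
consistently *between* treatments.
"""

import numpy as np

from evomet.cmh import scan
from evomet.filtering import filter_snps
from evomet.simulate import SimulationConfig, simulate

cfg = SimulationConfig(seed=42, n_snps=2000, n_causal_loci=8)
table, design, matrix, truth = simulate(cfg)
print(f"simulated {table.n_snps} SNPs x {table.n_populations} populations "
      f"({design.n_treatments} treatments x {design.n_strata} replicates)")

filt = filter_snps(table)  # 20-200x coverage, 2% pooled MAF
print(f"{filt.n_snps} SNPs pass the calling filters")

res = scan(filt, design)
top = np.argsort(res.Q)[::-1][:5]
print("\ntop 5 SNPs by CMH statistic (df = 2):")
for i in top:
    print(f"  {res.chrom[i]}:{res.pos[i]:>9}  Q={res.Q[i]:8.1f}  p={res.p[i]:.3g}")
print("\ncausal windows planted by the generator:", ", ".join(truth.causal_windows[:4]), "...")
print("A large Q at a planted window means the scan found the "
      "treatment-correlated frequency shift over the drift background.")
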