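"""Genetic differentiation among sites: Weir-Cockerham F_ST.

Simulates 6 sites under a Balding-Nichols island model with theta = 0.2,
clone-corrects, and estimates global and pairwise F_ST with a
permutation test.  The global estimate should recover ~0.2; the
linearized values F/(1-F) feed the downstream ordination.
"""

import numpy as np

from seascapegen import clonal, fstats
from seascapegen.simulate import GenotypeSimSpec, simulate_genotypes

genotypes, _ = simulate_genotypes(
    GenotypeSimSpec(n_sites=6, samples_per_site=48, n_loci=16, theta=0.2,
                    clonality=0.3, seed=7)
)
partition = clonal.identify_mlgs(genotypes, "permissive")
unique_mlgs = clonal.clone_correct(genotypes, partition)

result = fstats.fst(unique_mlgs, n_perm=199, seed=1, pairwise_perm=False)
print(f"global F_ST = {result.global_theta:.3f} (permutation p = {result.global_p:.3f})")
print("\npairwise F_ST:")
print(result.pairwise.to_frame().round(3).to_string())
lin = fstats.linearize_fst(result.pairwise)
print(f"\nlinearized F_ST range: {lin.condensed().min():.3f}-{lin.condensed().max():.3f}")
print("A significant p and estimates near the generating theta=0.2 show the "
      "variance-component estimator recovers among-site differentiation.")
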