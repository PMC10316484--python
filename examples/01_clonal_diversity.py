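"""Clone detection and per-site diversity on a simulated meadow panel.

Simulates 4 sites of 48 ramets genotyped at 16 microsatellite loci with
40% clonal replication, assigns multilocus genotypes (MLGs), and prints
the per-site diversity table: N ramets, G genets, clonal richness
R = (G-1)/(N-1), heterozygosities, the inbreeding coefficient F_IS and
the probability of identity.  Low R means many samples are ramets of the
same genet; PID_N << 1 means identical MLGs are clones rather than
chance sexual duplicates.
"""

from seascapegen import clonal
from seascapegen.simulate import GenotypeSimSpec, simulate_genotypes

genotypes, truth = simulate_genotypes(
    GenotypeSimSpec(n_sites=4, samples_per_site=48, n_loci=16,
                    theta=0.1, f=0.1, clonality=0.4, seed=42)
)
partition = clonal.identify_mlgs(genotypes, missing_policy="permissive")
table = clonal.site_diversity_table(genotypes, partition, rarefaction_g=(14,), n_perm=199, seed=1)

cols = ["site", "N", "G", "R", "nA", "A_R_14", "H_O", "H_NB", "F_IS", "PID_N"]
print(table[cols].round(3).to_string(index=False))
print(f"\ntrue clonal richness from the generator: {truth.true_clonal_richness():.3f}")
print("R close to the truth row-by-row shows MLG matching recovers the clonal structure.")
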