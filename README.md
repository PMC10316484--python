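# seascapegen

Seascape genetics of clonal marine plants: from codominant microsatellite
genotypes, simulated propagule dispersal on gridded ocean currents, and
habitat covariates to a variance partitioning of genetic differentiation
into geographic, oceanographic, and environmental components.

## Who this is for

Population geneticists and marine ecologists asking *why* sedentary,
water-dispersed organisms (seagrasses, corals, macroalgae) show genetic
structure at scales well inside their physical dispersal range.  Three
classes of driver compete: isolation by distance (GD), isolation by
oceanographic resistance (OC — currents constrain or facilitate propagule
transport regardless of distance), and isolation by environment (EN —
habitat filters migrants after arrival).  `seascapegen` implements the
full inference chain that separates them, plus a synthetic-data generator
so every stage is testable without field data or a hydrodynamic hindcast.

## The method

1. **Clonal structure.** Samples (ramets) are grouped into multilocus
   genotypes (MLGs = genets); clonal richness is R = (G−1)/(N−1).  The
   probability of identity PID = Π_l [Σ p_i⁴ + Σ_{i<j}(2p_i p_j)²] and
   the binomial-tail P_sex test decide whether repeated MLGs are clones
   or chance sexual duplicates.  Diversity (H_O; Nei's unbiased
   H_NB = (2n/(2n−1))(1−Σp²)), Weir–Cockerham F_IS with an allele-permutation
   test, hypergeometric rarefaction of allelic and private-allele richness,
   maximum-likelihood null-allele screening and the standardized index of
   association r̄_d complete the per-site summary.  Downstream analyses use
   unique MLGs only.
2. **Differentiation.** Global and pairwise F_ST by Weir & Cockerham
   (1984) variance components with individual-permutation tests;
   Rousset's linearization F/(1−F); the per-locus G_ST–H_S correlation as
   a mutation-bias diagnostic; Smouse–Peakall individual spatial
   autocorrelation over distance classes; the Evanno ΔK statistic on
   supplied clustering log-likelihoods.
3. **Dispersal.** Lagrangian particle tracking on hourly gridded currents
   (RK4 with sub-stepping, bilinear/linear interpolation, 1 m²/s random
   walk, 7-day competency window); directed connectivity C_ij = average
   particles released at site i detected in site j's 500 m cell per
   release; least-cost overwater distances by Dijkstra on the sea-cell
   lattice.
4. **Inference.** GS = PCoA of linearized F_ST (positive axes);
   GD = PCNM spatial eigenvectors of overwater distance; OC = PCA of
   connectivity-network metrics (strength, closeness, betweenness,
   transitivity); EN = correspondence-analysis axes of habitat dummies;
   Mantel tests of each driver against GS; then partial-RDA variance
   partitioning of "GS ~ GD + OC + EN" with Ezekiel-adjusted R²,
   marginal and conditional permutation F-tests, and all shared
   fractions by inclusion–exclusion.

## Worked example

```python
from seascapegen import AnalysisConfig, SimulationScenario, run_full_analysis

config = AnalysisConfig(seed=11, n_perm_fst=199, n_perm_mantel=999, n_perm_rda=999)
report = run_full_analysis(
    config, scenario=SimulationScenario(seed=11, connectivity_mode="grouped")
)
print(f"global F_ST = {report.fst.global_theta:.3f} (p = {report.fst.global_p})")
print(report.varpart.table().round(3).to_string(index=False))
```

prints (seed 11):

```
global F_ST = 0.088 (p = 0.005)
     effect         term  R2_adj_pct  df_mod  df_res      F     p
   Marginal           GD      -7.406     3.0     8.0  0.747 0.583
   Marginal           OC      82.226     3.0     8.0 17.963 0.002
   Marginal           EN      83.753     3.0     8.0 19.901 0.002
   Marginal     Residual      13.156     NaN     NaN    NaN   NaN
Conditional GD|(OC + EN)       0.593     3.0     2.0  1.075 0.477
Conditional OC|(GD + EN)       4.479     3.0     2.0  1.567 0.301
Conditional EN|(GD + OC)       7.806     3.0     2.0  1.989 0.194
```

Read it as: the sites are strongly differentiated (F_ST ≈ 0.09, p < 0.01);
oceanographic connectivity and habitat each explain ~80% of the
genetic-structure variance marginally, geography explains little, and no
driver is significant once the other two are controlled — ocean transport
and habitat explain the structure jointly, not separately.  The
`examples/` directory has one short script per capability (clonal
diversity, F_ST, particle dispersal, overwater/network metrics, variance
partitioning, spatial autocorrelation); each prints its numbers with a
line on what they mean.

A thin CLI wraps the same functions:

```bash
seascapegen simulate --seed 1 --outdir study
seascapegen all --seed 1 --outdir results
```

## Layout

```
src/seascapegen/   types, io, simulate, clonal, fstats, dispersal,
                   network, varpart, pipeline, cli
tests/             unit + property + acceptance suites
examples/          one narrative script per capability
docs/methods.md    models, assumptions, parameter choices, limitations
```
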