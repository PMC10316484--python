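# Methods

This note documents the models behind `seascapegen`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## 1. Clonal structure

**MLG assignment.** Two policies. *strict*: two samples share a
multilocus genotype only if all loci are equal and neither sample has
any missing call — any sample with missing data is its own MLG.
*permissive* (the pipeline default): missing loci act as wildcards and
groups are the transitive closure of pairwise compatibility, so a clone
whose genotype failed at one locus still joins its genet.  Closure is
order-independent; MLG labels follow first occurrence.  Samples missing
at every locus are flagged unassignable and excluded from G.

**Clonal richness.** R = (G−1)/(N−1): 0 for a monoclonal stand, 1 when
every ramet is a distinct genet.

**PID and P_sex.** Per-locus PID_l = Σ_i p_i⁴ + Σ_{i<j}(2p_i p_j)² (the
standard random-mating multi-allele form; the sibling variant is not
implemented).  Cumulative PID multiplies loci in observed or
most-informative-first order.  PID_N = N × cumulative PID is reported as
the expected number of chance MLG duplicates among N samples.  For an
MLG observed n times among N samples, P_gen is the single-draw genotype
probability with inbreeding correction (homozygote p² + f p(1−p);
heterozygote 2pq(1−f); f clamped at 0), and
P_sex = P[X ≥ n−1], X ~ Binomial(N−1, P_gen).  P_sex < 0.05 calls the
copies clone mates.

**Diversity.** Per locus: H_O = heterozygote fraction;
H_NB = (2n/(2n−1))(1−Σp²).  F_IS by Weir–Cockerham within-population
variance components summed over alleles and loci (monomorphic loci drop
out of the ratio); its permutation test shuffles allele copies among
individuals within the site, locus by locus (two-sided on |F_IS|,
add-one corrected, default 999 permutations).  All diversity and
differentiation statistics run on clone-corrected data (one
representative per site × MLG, the one with fewest missing calls).

**Rarefaction.** Allelic richness standardized to g individuals = 2g
gene copies by the hypergeometric expectation
Σ_a [1 − C(2n−N_a, 2g)/C(2n, 2g)], averaged over loci; private-allele
richness by the generalized (multi-site) form: expected alleles present
in this site's g-subsample and absent from every reference site's
g-subsample.  Standardization is on MLGs (not ramets) because the
clone-corrected genet sample is the meaningful unit; defaults g = 14
and 20.

**Null alleles.** An EM fit of the visible-allele + null-allele + failure
model: observed homozygotes mix true homozygotes and null heterozygotes,
observed blanks mix whole-sample failures (rate β) and null homozygotes.
Convergence at |Δlog L| < 1e−8 or 1000 iterations (non-convergence is
flagged, not raised).  Significance by likelihood-ratio test against
null frequency 0 using the ½χ²₁ boundary mixture.  At n ≈ 48 the
boundary-constrained point estimate has a half-distribution with ~0.03
spread, so a small but nonzero estimate is not evidence of null alleles
— the LRT is; parameter recovery is accurate by n ≈ 480.

**Index of association.** r̄_d = Σ_{l<m} cov(d_l, d_m) /
Σ_{l<m} √(var_l var_m) over per-locus pairwise allelic mismatch vectors
(0/1/2 per pair).  Samples with any missing call are excluded before
pair formation.  The permutation null shuffles allele copies among
individuals independently per locus (one-sided, add-one).

## 2. Differentiation

**F_ST.** Weir & Cockerham (1984) variance components (a, b, c) per
allele per locus, summed before the ratio; θ̂ = Σa/Σ(a+b+c).  A
GenAlEx-style AMOVA Φ on haploid-collapsed allele copies is available
(`estimator="amova"`); Weir–Cockerham is the default and the one used in
all recovery tests.  Permutation tests shuffle individuals (unique MLGs)
across sites; p is add-one corrected.  Sites with fewer than 2 samples
are excluded with a warning.  Pairwise estimates are reported raw
(`pairwise_raw`) but clamped at 0 in the matrix used for linearization
and PCoA, since F/(1−F) and metric embedding require nonnegative input.

**G_ST–H_S screen.** Per locus: H_S = mean within-site unbiased expected
heterozygosity; H_T from unweighted mean allele frequencies;
G_ST = (H_T−H_S)/H_T; r_GH = Pearson correlation across loci, with a
two-sided bootstrap over loci (add-one corrected).  A significantly
negative r_GH warns that high-mutation loci drag multi-locus F_ST down.
Note that under a pure drift model G_ST is mechanically constrained by
H_S, so moderately negative correlations arise without any mutation
effect; the screen is a diagnostic, not an estimator.

**Spatial autocorrelation.** Individual squared genetic distance = half
the squared Euclidean distance between per-locus allele-count vectors,
summed over loci (missing loci imputed with twice the pooled allele
frequencies); double-centering gives the covariance C.  Per distance
class h ((lower, upper] intervals over the configured endpoints),
r(h) = Σ_{pairs∈h} C_ij / Σ_{pairs∈h} (C_ii+C_jj)/2, which is 1 when a
class contains only clone-mate pairs.  The permutation null shuffles
individual locations jointly in rows and columns; bootstrap CIs resample
pairs within class.  The all-pairs single-class statistic equals the
brute-force Mantel-type global autocorrelation (tested).

**Evanno ΔK.** ΔK(K) = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| /
sd(L(K)) on a runs × K log-likelihood table; defined only for interior
K with positive run-to-run sd.  The clustering MCMC that produces the
table is outside this package's scope.

## 3. Dispersal

**Advection.** Per outer hour: RK4 integration of the bilinearly
(space) and linearly (time) interpolated velocity, split into
`substeps` sub-intervals (default 1; halving the sub-step cuts the
orbit-closure error ~16×, and the default already closes a 24 h
rotation orbit to 0.025%).  Velocities are zero on land cells, so the
interpolated field tapers to zero at the coast.  After advection, one
isotropic random-walk kick per hour with per-axis displacement
√(2KΔt)·z, K = 1 m²/s by default (applied once per hour, not per RK4
stage, so the noise process is well defined).  Land policy *freeze*
(default): a sub-step or kick that would land on a masked cell keeps the
previous position for that sub-step, and the particle may move later;
*beach* removes it permanently.  K = 0 trajectories are
seed-independent; fixed seeds give bit-identical output.

**Releases and connectivity.** Default schedule mirrors a spawning-season
design: 100 particles per site per release, 3-day intervals over a
153-day season (51 releases/year), repeatable over years; all
overridable, and scaled-down schedules are used throughout the tests.
Particles start uniformly inside the site's detection cell (a 500 m
square centered on the site).  C_ij averages, over release events, the
number of particles from i whose hourly fixes enter j's cell — counted
once per (release, particle, target) by default; `per_fix` counting and
the diagonal keep/zero choice are flags, since either convention is
defensible.

**Overwater distance.** Dijkstra on the sea-cell lattice (8- or
16-neighbor stencil; 16 adds knight moves whose two mid-cells must both
be sea, keeping discretization error of straight paths within ~2%).
Sites snap to the nearest sea cell within 2 cells; disconnected pairs
flag infinite distance.

## 4. Predictor blocks and variance partitioning

GS = PCoA (eigenvalues > 1e−8 × max retained) of linearized F_ST.
GD = PCNM: distances above t (default: longest minimum-spanning-tree
edge) replaced by 4t, PCoA, positive-eigenvalue eigenvectors as
predictors; the first 3 by default, or a correlation screen against GS
(threshold on max |r|) — both rules are exposed because "not collinear
with the response" is not a standard criterion.  OC = PCA (centered,
scaled; constant columns dropped) of four network metrics of the
directed connectivity matrix: strength = Σ_j(C_ij+C_ji);
closeness/betweenness on shortest paths with edge length = raw weight
(*cost* semantics, replicating the convention under which high closeness
means isolation; `cost_inverse` gives the conventional reading);
transitivity = local clustering on the binarized undirected graph.
Zero entries are absent edges, not zero-cost edges.  EN = correspondence
analysis of one-hot habitat categories plus range-scaled numeric
columns; first 3 axes.

With fewer than ~11 sites, 3 axes per block would exhaust the residual
degrees of freedom (n−1−9), so the pipeline uses
k = min(3, max(1, (n_sites−2)/3)) axes per block; at the 11–12 site
design this is 3, matching the reference analysis shape (marginal df
3/7–8, conditional df 3/1–2).

**RDA.**  R² = ‖fitted‖²/‖Y‖² from least squares of the centered
response on centered predictors (collinear columns dropped by pivoted
QR with a warning); adjusted by Ezekiel, 1−(1−R²)(n−1)/(n−m−1) with
m = predictor rank.  Partial R² is semipartial (fraction of the
*original* response variance), and conditional adjusted fractions are
differences of adjusted R² of nested models.  F for the marginal test is
(R²/m)/((1−R²)/(n−m−1)); for the conditional test the numerator is the
added SS over m and the denominator the full-model residual SS over
n−1−m−m_Z.  Permutations: marginal tests permute response rows;
conditional tests permute reduced-model residuals (Freedman–Lane); both
add-one corrected.  All 7 union R² values are computed; unique, pairwise
and triple shared fractions follow by inclusion–exclusion, and
unadjusted fractions sum to 1 to machine precision.  Adjusted fractions
may be negative and are reported as computed.  Union adjusted R² matches
R vegan's `RsquareAdj(rda(...))` to 1e−9 (cross-checked in the tests).

**Mantel.** Pearson correlation of off-diagonal upper triangles; joint
row/column permutation of one matrix; one-sided (greater) by default,
add-one corrected.

## 5. The synthetic generators

**Genotypes.** Per locus, ancestral frequencies ~ symmetric Dirichlet
over `alleles_per_locus` (default 5) alleles; site frequencies from the
multi-allele Balding–Nichols distribution Dirichlet(p(1−θ)/θ), giving
E[θ̂_WC] ≈ θ (verified: mean error < 0.02 at θ ∈ {0.05, 0.2}).
Optionally hierarchical: group frequencies drawn first with
θ_between, then sites within groups with θ.  Genotypes drawn with
inbreeding f (probability f of an autozygous draw).  With probability
`clonality` a sample copies the full MLG of an earlier same-site sample;
missingness is then re-drawn independently (default 2% per sample ×
locus), so clones share a genet but not a missing pattern.  Allele sizes
are even integers in locus-specific ranges — cosmetic dinucleotide
realism.  The truth record stores realized frequencies, clone donors and
genet labels, so R recovery is tested against the exact simulated truth.

**Currents.** Hourly u,v on a planar meter grid (default 2 km spacing):
residual flow plus a tidal sinusoid along a declared axis, with
`uniform`, `solid_rotation` and `tidal_channel` presets and an optional
land mask (zero velocity on land).

**Habitat.** Depth, Wentworth sediment class, geomorphic habitat type,
other-seagrass count, coral presence.  `association="grouped"` gives
each site group a distinct profile with disjoint sediment/habitat
supports so environmental dissimilarity aligns with the groups;
`"none"` draws all sites from one distribution (verified independent of
grouping by chi-square calibration).

**The default study scenario** (`SimulationScenario`) emulates the
target design: 12 sites × 48 ramets × 16 loci over an ~80 km domain,
θ_between = 0.15 and θ_within = 0.02 over two site groups, f = 0.1,
clonality 0.4, grouped habitat, and connectivity on the 0–7.5
particles-per-release scale in which group 0 is oceanographically
isolated (weak exchange even internally) and group 1 well connected —
the configuration where an isolated site cluster coincides with a
distinct genetic cluster.  Crucially the groups are spatially
*interleaved* along the coast, so low-frequency PCNM axes do not align
with group membership and geography genuinely fails to explain the
structure.  Connectivity can come from the particle simulation
(`connectivity_mode="particles"`) or be drawn directly from the group
structure (`"grouped"`), which the statistical tests use for speed.

**What the generator does not emulate.** Realistic bathymetry and
coastlines, seasonal/meteorological forcing beyond one sinusoid,
propagule buoyancy biology beyond the 7-day window, stepping-stone
mutation (allele frequencies are exchangeable across loci), linkage,
and genotyping artifacts beyond uniform missingness and the explicit
null-allele model.  Passing tests therefore demonstrate estimator
correctness and internal consistency under the stated models, not
robustness to the full messiness of field data.

## 6. Problem sizes in the test suite

Statistical tests run at deliberately modest sizes chosen to keep the
Monte-Carlo error small relative to each assertion's margin: estimator
recovery at the full 12 × 48 × 16 design over 20 seeds; the
variance-partitioning signature over 20 seeded end-to-end runs (99–499
permutations per test); permutation-calibration checks over 200 null
datasets at 99 permutations with Kolmogorov–Smirnov α = 0.01; dispersal
physics with 10⁴ particles.  All are computed fresh at test time; no
fixture data ships with the package.

## 7. Known limitations

- The Smouse–Peakall class statistic uses the pair-sum normalization
  described above; GenAlEx's exact weighting differs in small samples.
- The AMOVA Φ estimator collapses diploid genotypes to allele copies
  (Φ_PT-like); it is provided for comparability, not inference.
- Null-allele significance defaults to the analytic boundary LRT; the
  parametric bootstrap is available but slow at publication scale.
- PCNM eigenvectors are returned unweighted (unit norm); weighted
  dbMEM variants and forward selection with double stopping are out of
  scope, as are dbRDA/capscale response transformations.
- The CA encoding range-scales numeric habitat variables to [0, 1]
  before treating them as abundance-like columns; other encodings
  (fuzzy coding, standardization to unit inertia) would shift EN axis
  loadings.
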