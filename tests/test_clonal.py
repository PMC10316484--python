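"""Clone detection and per-site diversity statistics.

Expected values are hand arithmetic or brute-force enumeration computed
independently of the implementation (the oracles live in this file).
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seascapegen import clonal
from seascapegen.simulate import GenotypeSimSpec, simulate_genotypes
from seascapegen.types import ValidationError

from conftest import make_genotypes


# ------------------------------------------------------------------ MLGs

def brute_force_match(gt, policy):
    """O(N^2) reference matcher: transitive closure over pairwise
    compatibility."""
    n = gt.n_samples
    miss = gt.missing
    geno = np.sort(gt.alleles, axis=2)
    groups = [{i} for i in range(n)]

    def compatible(i, j):
        if policy == "strict":
            if miss[i].any() or miss[j].any():
                return False
            return np.array_equal(geno[i], geno[j])
        for l in range(gt.n_loci):
            if miss[i, l] or miss[j, l]:
                continue
            if not np.array_equal(geno[i, l], geno[j, l]):
                return False
        return not (miss[i].all() or miss[j].all())

    for i, j in itertools.combinations(range(n), 2):
        if compatible(i, j):
            gi = next(g for g in groups if i in g)
            gj = next(g for g in groups if j in g)
            if gi is not gj:
                groups.remove(gj)
                gi |= gj
    return sorted(
        (frozenset(g) for g in groups if not miss[list(g)[0]].all() or len(g) > 1),
        key=min,
    )


class TestIdentifyMlgs:
    def test_all_identical_gives_one_mlg(self):
        gt = make_genotypes([[[100, 102], [200, 200]]] * 5)
        assert clonal.identify_mlgs(gt, "strict").g_total == 1

    def test_all_distinct_gives_n_mlgs(self):
        gt = make_genotypes([[[100 + 2 * i, 100 + 2 * i], [200, 200]] for i in range(6)])
        assert clonal.identify_mlgs(gt, "strict").g_total == 6

    def test_wildcard_joins_in_permissive_but_not_strict(self):
        # A == B everywhere; C differs from A at locus 1 but is missing there
        gt = make_genotypes(
            [
                [[100, 102], [200, 200]],  # A
                [[100, 102], [200, 200]],  # B
                [[100, 102], [0, 0]],      # C: wildcard at locus 2
            ]
        )
        strict = clonal.identify_mlgs(gt, "strict")
        permissive = clonal.identify_mlgs(gt, "permissive")
        assert strict.mlg_id[2] != strict.mlg_id[0]
        assert strict.g_total == 2  # A,B share; C alone
        assert permissive.g_total == 1  # C joins via wildcard

    @pytest.mark.parametrize("policy", ["strict", "permissive"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_matcher(self, policy, seed):
        rng = np.random.default_rng(seed)
        n = 40
        base = rng.integers(0, 3, size=(8, 4, 2)) * 2 + 100  # few distinct MLGs
        idx = rng.integers(0, 8, size=n)
        alleles = base[idx].copy()
        alleles[rng.random((n, 4)) < 0.15] = 0
        gt = make_genotypes(alleles)
        part = clonal.identify_mlgs(gt, policy)
        ours = sorted((frozenset(v) for v in part.groups().values()), key=min)
        assert ours == brute_force_match(gt, policy)

    def test_all_missing_sample_unassignable(self):
        gt = make_genotypes([[[100, 100]], [[0, 0]]])
        with pytest.warns(UserWarning, match="unassignable"):
            part = clonal.identify_mlgs(gt, "permissive")
        assert part.mlg_id[1] == -1
        assert part.g_total == 1


class TestClonalRichness:
    @pytest.mark.parametrize(
        "n,g,expected",
        [
            (557, 319, 0.57),  # study-wide totals
            (48, 33, 0.68),
            (48, 23, 0.47),
            (48, 18, 0.36),
            (48, 32, 0.66),
            (48, 44, 0.91),
        ],
    )
    def test_published_site_values(self, n, g, expected):
        assert round(clonal.clonal_richness(n, g), 2) == expected

    def test_monoclonal_site_is_zero(self):
        assert clonal.clonal_richness(30, 1) == 0.0

    def test_requires_two_samples(self):
        with pytest.raises(ValidationError):
            clonal.clonal_richness(1, 1)


# ------------------------------------------------------------- PID / Psex

def brute_force_pid(freq_lists):
    """Enumerate all ordered genotype pairs; P[same multilocus genotype]."""
    total = 1.0
    for freqs in freq_lists:
        p_same = 0.0
        alleles = list(freqs)
        for a, b in itertools.product(alleles, repeat=2):
            g_prob = freqs[a] * freqs[b]
            for c, d in itertools.product(alleles, repeat=2):
                if {a, b} == {c, d} and sorted((a, b)) == sorted((c, d)):
                    p_same += g_prob * freqs[c] * freqs[d]
        total *= p_same
    return total


class TestProbabilityOfIdentity:
    def test_monomorphic_locus_pid_one(self):
        gt = make_genotypes([[[100, 100]]] * 4)
        pid_l, cum, _ = clonal.probability_of_identity(gt)
        assert pid_l[0] == 1.0

    def test_biallelic_half_half(self):
        # p = q = 0.5: PID = 2(0.5^4) + (2*0.25)^2 = 0.375
        gt = make_genotypes([[[100, 100]], [[102, 102]], [[100, 102]], [[102, 100]]])
        pid_l, cum, pid_n = clonal.probability_of_identity(gt)
        assert pid_l[0] == pytest.approx(0.375)
        assert pid_n == pytest.approx(4 * 0.375)
        assert pid_l[0] == pytest.approx(brute_force_pid([{100: 0.5, 102: 0.5}]))

    def test_two_independent_loci_multiply(self):
        gt = make_genotypes(
            [[[100, 100], [200, 200]], [[102, 102], [202, 202]],
             [[100, 102], [200, 202]], [[102, 100], [202, 200]]]
        )
        _, cum, _ = clonal.probability_of_identity(gt)
        assert cum[-1] == pytest.approx(0.375**2) == pytest.approx(0.140625)
        assert cum[-1] == pytest.approx(
            brute_force_pid([{100: 0.5, 102: 0.5}, {200: 0.5, 202: 0.5}])
        )

    def test_cumulative_nonincreasing_and_information_order(self):
        gt, _ = simulate_genotypes(GenotypeSimSpec(n_sites=1, samples_per_site=30, n_loci=8, seed=2))
        _, cum, _ = clonal.probability_of_identity(gt, locus_order="increasing-information")
        assert np.all(np.diff(cum) <= 1e-15)


class TestPgenPsex:
    def test_pgen_hwe_homozygous_product(self):
        freqs = [{100: 0.3, 102: 0.7}, {200: 0.6, 202: 0.4}]
        mlg = np.array([[100, 100], [202, 202]])
        assert clonal.p_gen(mlg, freqs, f=0.0) == pytest.approx(0.3**2 * 0.4**2)

    def test_pgen_single_het_half(self):
        assert clonal.p_gen(np.array([[100, 102]]), [{100: 0.5, 102: 0.5}], f=0.0) == pytest.approx(0.5)

    def test_full_inbreeding_forbids_hets(self):
        assert clonal.p_gen(np.array([[100, 102]]), [{100: 0.5, 102: 0.5}], f=1.0) == 0.0

    def test_psex_binomial_tail_value(self):
        # n=2 of N=10, pgen=0.1: 1 - 0.9^9 (direct summation oracle)
        direct = 1.0 - 0.9**9
        assert clonal.p_sex(2, 10, 0.1) == pytest.approx(direct)

    def test_psex_certain_when_pgen_one(self):
        assert clonal.p_sex(3, 20, 1.0) == 1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=2, max_value=8),
        st.integers(min_value=10, max_value=40),
        st.floats(min_value=1e-4, max_value=0.5),
    )
    def test_psex_monotonicities(self, n, N, pgen):
        base = clonal.p_sex(n, N, pgen)
        assert clonal.p_sex(n, N, min(pgen * 1.5, 1.0)) >= base  # up in pgen
        assert clonal.p_sex(n, N + 5, pgen) >= base  # up in N
        if n + 1 <= N:
            assert clonal.p_sex(n + 1, N, pgen) <= base  # down in n


# ------------------------------------------------------- diversity stats

class TestDiversityStats:
    def test_all_heterozygote_locus(self):
        # 10 samples all AB: H_O = 1, H_NB = (20/19)(1 - 0.5) = 0.5263, F_IS < 0
        gt = make_genotypes([[[100, 102]]] * 10)
        h_o, h_nb, f_is, _, per_locus = clonal.diversity_stats(gt, n_perm=0)
        assert h_o == 1.0
        assert h_nb == pytest.approx(20 / 19 * 0.5)
        assert f_is < 0

    def test_monomorphic_locus_excluded_from_fis(self):
        gt = make_genotypes([[[100, 100], [200, 202]], [[100, 100], [200, 202]],
                             [[100, 100], [202, 202]], [[100, 100], [200, 200]]])
        h_o, h_nb, f_is, _, per_locus = clonal.diversity_stats(gt, n_perm=0)
        assert per_locus.loc[0, "H_O"] == 0.0
        assert per_locus.loc[0, "H_NB"] == 0.0
        assert np.isfinite(f_is)

    def test_inbreeding_recovery(self):
        """F_IS-hat recovers the generator's inbreeding coefficient."""
        est = []
        for seed in range(6):
            gt, _ = simulate_genotypes(
                GenotypeSimSpec(n_sites=1, samples_per_site=80, n_loci=12, theta=0.0,
                                f=0.4, clonality=0.0, missing_rate=0.0, seed=seed)
            )
            est.append(clonal.diversity_stats(gt, n_perm=0)[2])
        assert abs(np.mean(est) - 0.4) < 0.05


# --------------------------------------------------------- rarefaction

def enumerate_rarefaction(allele_counts, g_genes):
    """Expected distinct alleles over all subsets of g gene copies."""
    pool = [a for a, c in allele_counts.items() for _ in range(c)]
    vals = [len(set(combo)) for combo in itertools.combinations(range(len(pool)), g_genes)]
    labels = [len({pool[i] for i in combo}) for combo in itertools.combinations(range(len(pool)), g_genes)]
    return np.mean(labels)


class TestRarefaction:
    def test_matches_exhaustive_enumeration(self):
        # 2 alleles with copy counts (3, 1) in n=2 diploids, g=1 (2 genes)
        gt = make_genotypes([[[100, 100]], [[100, 102]]])
        expected = enumerate_rarefaction({100: 3, 102: 1}, 2)
        assert expected == pytest.approx(1.5)
        assert clonal.rarefied_richness(gt, g=1) == pytest.approx(expected)

    def test_full_sample_returns_observed_count(self):
        gt = make_genotypes([[[100, 102]], [[104, 100]], [[102, 104]]])
        assert clonal.rarefied_richness(gt, g=3) == pytest.approx(3.0)

    def test_monomorphic_full_sample_is_one(self):
        gt = make_genotypes([[[100, 100]]] * 5)
        assert clonal.rarefied_richness(gt, g=5) == pytest.approx(1.0)

    def test_never_exceeds_observed_richness(self):
        gt, _ = simulate_genotypes(GenotypeSimSpec(n_sites=1, samples_per_site=25, n_loci=6,
                                                   missing_rate=0.0, seed=8))
        observed = np.mean([len(d) for d in clonal.allele_counts(gt)])
        for g in (5, 10, 20):
            assert clonal.rarefied_richness(gt, g=g) <= observed + 1e-12

    def test_g_beyond_sample_errors(self):
        gt = make_genotypes([[[100, 102]]] * 3)
        with pytest.raises(ValidationError, match="exceeds"):
            clonal.rarefied_richness(gt, g=4)

    def test_private_alleles_disjoint_sites(self):
        a = make_genotypes([[[100, 100]]] * 6)
        b = make_genotypes([[[102, 102]]] * 6)
        # every allele of a is private relative to b
        assert clonal.rarefied_richness(a, g=4, private=True, reference=[b]) == pytest.approx(1.0)


# --------------------------------------------------------- null alleles

class TestNullAlleleML:
    def test_all_heterozygous_estimates_zero(self):
        rng = np.random.default_rng(0)
        alleles = np.stack([np.full(30, 100), np.full(30, 102)], axis=1)[:, None, :]
        gt = make_genotypes(alleles)
        fit = clonal.null_allele_ml(gt, 0)
        assert fit.null_freq < 1e-3
        assert fit.converged

    def test_null_free_data_calibration(self):
        """Simulated without null alleles: the likelihood-ratio test stays
        calibrated (few false positives) and the boundary-constrained ML
        estimate is typically small."""
        seeds = 30
        est, sig = [], 0
        for seed in range(seeds):
            gt, _ = simulate_genotypes(
                GenotypeSimSpec(n_sites=1, samples_per_site=48, n_loci=1,
                                alleles_per_locus=4, theta=0.0, missing_rate=0.01, seed=seed)
            )
            fit = clonal.null_allele_ml(gt, 0)
            est.append(fit.null_freq)
            sig += fit.p_value <= 0.05
        assert sig <= 0.15 * seeds
        assert np.median(est) < 0.02

    def test_recovers_simulated_null_frequency(self):
        """Null allele at frequency 0.15 hidden in the data: observed
        homozygote excess and blanks let EM recover it at n=480."""
        rng = np.random.default_rng(42)
        n = 480
        freqs = np.array([0.4, 0.3, 0.15, 0.15])  # last is the null allele
        sizes = np.array([100, 102, 104, -1])
        est = []
        for rep in range(5):
            draws = rng.choice(4, size=(n, 2), p=freqs)
            obs = np.empty((n, 1, 2), dtype=int)
            for i, (a, b) in enumerate(draws):
                if a == 3 and b == 3:
                    obs[i, 0] = (0, 0)  # null homozygote reads as blank
                elif a == 3:
                    obs[i, 0] = (sizes[b], sizes[b])  # null het reads homozygous
                elif b == 3:
                    obs[i, 0] = (sizes[a], sizes[a])
                else:
                    obs[i, 0] = (sizes[a], sizes[b])
            fit = clonal.null_allele_ml(make_genotypes(obs), 0)
            est.append(fit.null_freq)
        assert abs(np.mean(est) - 0.15) < 0.05


# -------------------------------------------- index of association

class TestIndexOfAssociation:
    def test_duplicated_locus_gives_one(self):
        rng = np.random.default_rng(1)
        locus = rng.integers(0, 3, size=(25, 1, 2)) * 2 + 100
        alleles = np.concatenate([locus, locus + 100], axis=1)  # perfectly linked copy
        gt = make_genotypes(alleles)
        rd, _ = clonal.index_of_association_rd(gt, n_perm=0)
        assert rd == pytest.approx(1.0)

    def test_single_locus_errors(self):
        gt = make_genotypes([[[100, 102]]] * 5)
        with pytest.raises(ValidationError):
            clonal.index_of_association_rd(gt, n_perm=0)

    def test_independent_loci_near_zero_with_null_p(self):
        gt, _ = simulate_genotypes(
            GenotypeSimSpec(n_sites=1, samples_per_site=40, n_loci=8, theta=0.0,
                            clonality=0.0, missing_rate=0.0, seed=12)
        )
        rd, p = clonal.index_of_association_rd(gt, n_perm=199, seed=5)
        assert abs(rd) < 0.1
        assert p > 0.01
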