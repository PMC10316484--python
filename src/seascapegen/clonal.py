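"""Clone detection and per-site genotypic/genetic diversity statistics.

Covers the classic descriptors of a partially clonal microsatellite
dataset: multilocus genotype (MLG) assignment, clonal richness
R = (G-1)/(N-1), the probability of identity and P_sex clone-mate test,
observed and Nei unbiased heterozygosity, the Weir & Cockerham
within-population inbreeding coefficient with a permutation test,
hypergeometric rarefaction of allelic and private-allele richness,
maximum-likelihood null-allele estimation, and the standardized index of
association r_bar_d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeTable, ValidationError

__all__ = [
    "MLGPartition",
    "NullAlleleFit",
    "identify_mlgs",
    "clonal_richness",
    "allele_frequencies",
    "probability_of_identity",
    "p_gen",
    "p_sex",
    "diversity_stats",
    "rarefied_richness",
    "null_allele_ml",
    "index_of_association_rd",
    "site_diversity_table",
]


# ------------------------------------------------------------------ MLGs

@dataclass
class MLGPartition:
    """Assignment of samples to multilocus genotypes.

    ``mlg_id`` is -1 for unassignable samples (all loci missing).
    """

    mlg_id: np.ndarray  # (n,) int
    sample_id: np.ndarray
    site_id: np.ndarray
    policy: str

    @property
    def g_total(self) -> int:
        ids = self.mlg_id[self.mlg_id >= 0]
        return len(np.unique(ids))

    def g_by_site(self) -> dict[str, int]:
        out = {}
        for site in dict.fromkeys(self.site_id.tolist()):
            m = (self.site_id == site) & (self.mlg_id >= 0)
            out[site] = len(np.unique(self.mlg_id[m]))
        return out

    def groups(self) -> dict[int, list[int]]:
        """MLG id -> member sample row indices."""
        out: dict[int, list[int]] = {}
        for i, g in enumerate(self.mlg_id):
            if g >= 0:
                out.setdefault(int(g), []).append(i)
        return out

    def max_group_size_by_site(self) -> dict[str, int]:
        out = {}
        for site in dict.fromkeys(self.site_id.tolist()):
            m = (self.site_id == site) & (self.mlg_id >= 0)
            if m.sum() == 0:
                out[site] = 0
                continue
            _, counts = np.unique(self.mlg_id[m], return_counts=True)
            out[site] = int(counts.max())
        return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # smaller root wins -> deterministic labels
            if ri < rj:
                self.parent[rj] = ri
            else:
                self.parent[ri] = rj


def identify_mlgs(gt: GenotypeTable, missing_policy: str = "strict") -> MLGPartition:
    """Partition samples into multilocus genotypes.

    strict: two samples share an MLG iff all loci are equal and neither
    has missing data anywhere.  permissive: missing loci act as wildcards
    and groups are the transitive closure of pairwise compatibility.
    Samples missing at every locus are unassignable (mlg_id = -1).
    MLG ids are assigned in order of each group's first sample.
    """
    if missing_policy not in ("strict", "permissive"):
        raise ValueError("missing_policy must be 'strict' or 'permissive'")
    n = gt.n_samples
    miss = gt.missing  # (n, L)
    all_missing = miss.all(axis=1)
    # canonicalize: sort the two alleles within each locus
    geno = np.sort(gt.alleles, axis=2)  # (n, L, 2)

    uf = _UnionFind(n)
    if missing_policy == "strict":
        clean = ~miss.any(axis=1)
        keys: dict[tuple, int] = {}
        for i in np.flatnonzero(clean):
            key = tuple(geno[i].ravel())
            if key in keys:
                uf.union(keys[key], i)
            else:
                keys[key] = i
    else:
        # pairwise compatibility with wildcards, O(n^2) vectorized per row
        flat = geno.reshape(n, -1)
        miss2 = np.repeat(miss, 2, axis=1)  # missing flag per allele column
        for i in range(n):
            if all_missing[i]:
                continue
            j = np.arange(i + 1, n)
            if len(j) == 0:
                continue
            equal = flat[j] == flat[i]
            ok = equal | miss2[j] | miss2[i]
            compatible = ok.all(axis=1) & ~all_missing[i + 1 :]
            for jj in j[compatible]:
                uf.union(i, jj)

    roots = np.array([uf.find(i) for i in range(n)])
    roots[all_missing] = -1
    if all_missing.any():
        warnings.warn(f"{int(all_missing.sum())} sample(s) missing at all loci are unassignable")
    # relabel by first occurrence
    mlg_id = np.full(n, -1, dtype=np.int64)
    label = {}
    for i in range(n):
        if roots[i] < 0:
            continue
        r = roots[i]
        if r not in label:
            label[r] = len(label)
        mlg_id[i] = label[r]
    return MLGPartition(mlg_id=mlg_id, sample_id=gt.sample_id, site_id=gt.site_id, policy=missing_policy)


def clone_correct(gt: GenotypeTable, partition: MLGPartition) -> GenotypeTable:
    """Keep one representative per (site, MLG): the sample with the fewest
    missing loci (first occurrence breaks ties).  Unassignable samples
    are dropped."""
    miss_count = gt.missing.sum(axis=1)
    keep: list[int] = []
    best: dict[tuple, int] = {}
    for i in range(gt.n_samples):
        if partition.mlg_id[i] < 0:
            continue
        key = (gt.site_id[i], int(partition.mlg_id[i]))
        if key not in best or miss_count[i] < miss_count[best[key]]:
            best[key] = i
    keep = sorted(best.values())
    return gt.subset(np.array(keep, dtype=int))


def clonal_richness(n: int, g: int) -> float:
    """Clonal (genotypic) richness R = (G-1)/(N-1)."""
    if n < 2:
        raise ValidationError("clonal richness needs N >= 2")
    if g < 1 or g > n:
        raise ValidationError("G must be in [1, N]")
    return (g - 1) / (n - 1)


# -------------------------------------------------------- allele freqs

def allele_frequencies(gt: GenotypeTable) -> list[dict[int, float]]:
    """Per-locus allele relative frequencies from non-missing calls."""
    out = []
    miss = gt.missing
    for l in range(gt.n_loci):
        vals = gt.alleles[~miss[:, l], l, :].ravel()
        if len(vals) == 0:
            out.append({})
            continue
        alleles, counts = np.unique(vals, return_counts=True)
        tot = counts.sum()
        out.append({int(a): c / tot for a, c in zip(alleles, counts)})
    return out


def allele_counts(gt: GenotypeTable) -> list[dict[int, int]]:
    """Per-locus allele copy counts from non-missing calls."""
    out = []
    miss = gt.missing
    for l in range(gt.n_loci):
        vals = gt.alleles[~miss[:, l], l, :].ravel()
        alleles, counts = np.unique(vals, return_counts=True)
        out.append({int(a): int(c) for a, c in zip(alleles, counts)})
    return out


# ----------------------------------------------------------- PID / Psex

def probability_of_identity(
    gt: GenotypeTable, locus_order: str = "observed"
) -> tuple[np.ndarray, np.ndarray, float]:
    """Probability that two random individuals share a multilocus genotype.

    Per locus, PID_l = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2 (unbiased
    random-mating form); the cumulative PID is the product over included
    loci, in the given order ("observed" keeps input order,
    "increasing-information" adds the most informative — lowest PID_l —
    first).  Returns (per-locus PID, cumulative PID, PID_N) where
    PID_N = N x cumulative PID is the expected number of samples sharing
    an MLG by chance.
    """
    freqs = allele_frequencies(gt)
    pid_l = np.empty(gt.n_loci)
    for l, fr in enumerate(freqs):
        if not fr:
            raise ValidationError(f"locus {gt.locus_names[l]} has no genotyped samples")
        p = np.array(list(fr.values()))
        hom = np.sum(p**4)
        outer = np.outer(p, p)
        het = np.sum((2 * outer[np.triu_indices(len(p), k=1)]) ** 2)
        pid_l[l] = hom + het
    if locus_order == "increasing-information":
        order = np.argsort(pid_l)
    elif locus_order == "observed":
        order = np.arange(gt.n_loci)
    else:
        raise ValueError("locus_order must be 'observed' or 'increasing-information'")
    cumulative = np.cumprod(pid_l[order])
    pid_n = gt.n_samples * cumulative[-1]
    return pid_l, cumulative, float(pid_n)


def p_gen(
    mlg: np.ndarray, freqs: list[dict[int, float]], f: float = 0.0
) -> float:
    """Probability of one sexual origin of an MLG under inbreeding f.

    Per locus: homozygote p_i^2 + f p_i (1 - p_i); heterozygote
    2 p_i p_j (1 - f).  f is clamped to >= 0 (round-robin F_IS
    correction).  Missing loci are skipped.
    """
    f = max(float(f), 0.0)
    mlg = np.asarray(mlg)
    prob = 1.0
    for l in range(mlg.shape[0]):
        a, b = int(mlg[l, 0]), int(mlg[l, 1])
        if a == 0 or b == 0:
            continue
        fr = freqs[l]
        if a not in fr or b not in fr:
            raise ValidationError(f"allele {a if a not in fr else b} absent from frequency table at locus {l}")
        if a == b:
            p = fr[a]
            prob *= p * p + f * p * (1 - p)
        else:
            prob *= 2 * fr[a] * fr[b] * (1 - f)
    return prob


def p_sex(n: int, n_samples: int, pgen: float) -> float:
    """Probability that n copies of an MLG among N samples arose through
    independent sexual events: P[X >= n-1], X ~ Binomial(N-1, pgen)."""
    if n < 2:
        raise ValidationError("P_sex needs at least 2 copies of the MLG")
    if not (0 < pgen <= 1):
        raise ValidationError("pgen must be in (0, 1]")
    if n > n_samples:
        raise ValidationError("n cannot exceed the number of samples")
    return float(stats.binom.sf(n - 2, n_samples - 1, pgen))


# ------------------------------------------------- heterozygosity / F_IS

def _wc_single_pop_components(gt: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Weir & Cockerham within-population variance components (b, c)
    summed over alleles, one pair per locus.  f = 1 - sum(c)/sum(b+c)."""
    miss = gt.missing
    b_l = np.zeros(gt.n_loci)
    c_l = np.zeros(gt.n_loci)
    for l in range(gt.n_loci):
        rows = ~miss[:, l]
        n = int(rows.sum())
        if n < 2:
            b_l[l] = np.nan
            c_l[l] = np.nan
            continue
        g = gt.alleles[rows, l, :]
        alleles = np.unique(g)
        het = g[:, 0] != g[:, 1]
        for a in alleles:
            cnt = (g == a).sum()
            p = cnt / (2 * n)
            h = (het & ((g == a).any(axis=1))).sum() / n  # freq of hets carrying a
            b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            c = h / 2
            b_l[l] += b
            c_l[l] += c
    return b_l, c_l


def diversity_stats(
    gt: GenotypeTable,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float, float, float | None, pd.DataFrame]:
    """Observed/unbiased heterozygosity and Weir-Cockerham F_IS for the
    samples of one site.

    Returns (mean H_O, mean H_NB, F_IS, permutation p, per-locus frame).
    H_NB is Nei's unbiased expected heterozygosity
    (2n/(2n-1)) (1 - sum p_i^2).  The F_IS permutation test shuffles
    allele copies among individuals within the site, locus by locus
    (two-sided on |F_IS|, add-one corrected); pass n_perm=0 to skip.
    """
    miss = gt.missing
    L = gt.n_loci
    ho = np.full(L, np.nan)
    hnb = np.full(L, np.nan)
    na = np.zeros(L, dtype=int)
    for l in range(L):
        rows = ~miss[:, l]
        n = int(rows.sum())
        if n == 0:
            raise ValidationError(f"locus {gt.locus_names[l]} entirely missing at this site")
        g = gt.alleles[rows, l, :]
        na[l] = len(np.unique(g))
        ho[l] = float((g[:, 0] != g[:, 1]).mean())
        _, counts = np.unique(g, return_counts=True)
        p = counts / (2 * n)
        if n >= 2:
            hnb[l] = (2 * n / (2 * n - 1)) * (1 - np.sum(p**2))
        else:
            hnb[l] = np.nan

    def fis_of(table: GenotypeTable) -> float:
        b, c = _wc_single_pop_components(table)
        valid = ~np.isnan(b)
        denom = np.nansum(b[valid] + c[valid])
        if denom <= 0:
            return np.nan
        return 1.0 - np.nansum(c[valid]) / denom

    f_obs = fis_of(gt)
    p_val = None
    if n_perm and not np.isnan(f_obs):
        rng = np.random.default_rng(seed)
        hits = 0
        alleles = gt.alleles.copy()
        for _ in range(n_perm):
            perm = alleles.copy()
            for l in range(L):
                rows = np.flatnonzero(~miss[:, l])
                pool = alleles[rows, l, :].ravel()
                pool = rng.permutation(pool)
                perm[rows, l, :] = pool.reshape(-1, 2)
            f_p = fis_of(GenotypeTable(gt.sample_id, gt.site_id, gt.locus_names, perm))
            if not np.isnan(f_p) and abs(f_p) >= abs(f_obs):
                hits += 1
        p_val = (hits + 1) / (n_perm + 1)

    per_locus = pd.DataFrame(
        {"locus": gt.locus_names, "n_alleles": na, "H_O": ho, "H_NB": hnb}
    )
    return float(np.nanmean(ho)), float(np.nanmean(hnb)), float(f_obs), p_val, per_locus


# -------------------------------------------------------- rarefaction

def _prob_absent(n_copies: int, allele_count: int, draw: int) -> float:
    """P[allele absent from a draw of `draw` gene copies out of n_copies],
    i.e. C(n_copies - allele_count, draw) / C(n_copies, draw)."""
    if allele_count <= 0:
        return 1.0
    if n_copies - allele_count < draw:
        return 0.0
    # stable product form of the binomial ratio
    i = np.arange(draw)
    return float(np.prod((n_copies - allele_count - i) / (n_copies - i)))


def rarefied_richness(
    gt: GenotypeTable,
    g: int,
    private: bool = False,
    reference: list[GenotypeTable] | None = None,
) -> float:
    """Hypergeometric rarefaction of allelic richness to g individuals
    (2g gene copies), averaged across loci.

    With ``private=True``, computes rarefied private-allele richness
    following Kalinowski's generalized rarefaction: the expected number of
    alleles present in the g-subsample of this site but absent from
    g-subsamples of every reference site.
    """
    if private and not reference:
        raise ValidationError("private-allele rarefaction needs reference sites")
    counts = allele_counts(gt)
    ref_counts = [allele_counts(r) for r in reference] if private else []
    L = gt.n_loci
    vals = np.zeros(L)
    miss = gt.missing
    for l in range(L):
        n2 = int((~miss[:, l]).sum()) * 2
        if g * 2 > n2:
            raise ValidationError(f"g={g} exceeds the {n2 // 2} genotyped MLGs at locus {gt.locus_names[l]}")
        total = 0.0
        for a, c in counts[l].items():
            q_here = 1.0 - _prob_absent(n2, c, 2 * g)
            if private:
                p_absent_elsewhere = 1.0
                for rc, rt in zip(ref_counts, reference):
                    rn2 = int((~rt.missing[:, l]).sum()) * 2
                    if 2 * g > rn2:
                        raise ValidationError(f"g={g} exceeds genotyped MLGs at a reference site, locus {gt.locus_names[l]}")
                    q_there = 1.0 - _prob_absent(rn2, rc[l].get(a, 0), 2 * g)
                    p_absent_elsewhere *= 1.0 - q_there
                total += q_here * p_absent_elsewhere
            else:
                total += q_here
        vals[l] = total
    return float(vals.mean())


# ------------------------------------------------------- null alleles

@dataclass
class NullAlleleFit:
    """Maximum-likelihood null-allele fit for one locus."""

    null_freq: float
    beta: float  # genotyping-failure rate
    log_likelihood: float
    converged: bool
    p_value: float
    visible_freqs: dict[int, float]
    n_iter: int


def _null_loglik(obs_het, obs_hom, n_blank, p, pn, beta):
    """Log-likelihood of the Kalinowski-Taper observation model."""
    ll = 0.0
    for (a, b), cnt in obs_het.items():
        ll += cnt * np.log(max((1 - beta) * 2 * p[a] * p[b], 1e-300))
    for a, cnt in obs_hom.items():
        ll += cnt * np.log(max((1 - beta) * (p[a] ** 2 + 2 * p[a] * pn), 1e-300))
    if n_blank:
        ll += n_blank * np.log(max(beta + (1 - beta) * pn**2, 1e-300))
    return ll


def null_allele_ml(
    gt: GenotypeTable,
    locus: int,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> NullAlleleFit:
    """EM fit of the Kalinowski-Taper null-allele model at one locus.

    Observed homozygote counts are inflated by null heterozygotes and
    observed blanks by null homozygotes plus a failure rate beta.
    Significance is a likelihood-ratio test against null_freq = 0
    (one-degree boundary chi-square).
    """
    miss = gt.missing[:, locus]
    g = gt.alleles[~miss, locus, :]
    n_blank = int(miss.sum())
    n_typed = g.shape[0]
    if n_typed < 2:
        raise ValidationError("need at least 2 genotyped samples")
    if n_typed < 10:
        warnings.warn("fewer than 10 genotyped samples: null-allele estimate unreliable")
    n = n_typed + n_blank

    obs_het: dict[tuple[int, int], int] = {}
    obs_hom: dict[int, int] = {}
    for a, b in np.sort(g, axis=1):
        if a == b:
            obs_hom[int(a)] = obs_hom.get(int(a), 0) + 1
        else:
            obs_het[(int(a), int(b))] = obs_het.get((int(a), int(b)), 0) + 1
    alleles = sorted(set([a for ab in obs_het for a in ab]) | set(obs_hom))

    # init: observed frequencies, small null freq
    cnt = {a: 0.0 for a in alleles}
    for (a, b), c in obs_het.items():
        cnt[a] += c
        cnt[b] += c
    for a, c in obs_hom.items():
        cnt[a] += 2 * c
    tot = sum(cnt.values())
    p = {a: cnt[a] / tot for a in alleles}
    pn = 0.05
    p = {a: v * (1 - pn) for a, v in p.items()}
    beta = max(n_blank / n * 0.5, 1e-6)

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: expected allele copy counts and failures
        e_cnt = {a: 0.0 for a in alleles}
        e_null = 0.0
        e_fail = 0.0
        for (a, b), c in obs_het.items():
            e_cnt[a] += c
            e_cnt[b] += c
        for a, c in obs_hom.items():
            denom = p[a] ** 2 + 2 * p[a] * pn
            w_null = (2 * p[a] * pn / denom) if denom > 0 else 0.0
            e_cnt[a] += c * (2 * (1 - w_null) + 1 * w_null)
            e_null += c * w_null
        if n_blank:
            denom = beta + (1 - beta) * pn**2
            w_nullhom = ((1 - beta) * pn**2 / denom) if denom > 0 else 0.0
            e_null += n_blank * w_nullhom * 2
            e_fail = n_blank * (1 - w_nullhom)
        # M-step
        typed_equiv = n - e_fail  # expected genotyped individuals
        tot_alleles = 2 * typed_equiv
        if tot_alleles <= 0:
            break
        p = {a: e_cnt[a] / tot_alleles for a in alleles}
        pn = e_null / tot_alleles
        beta = e_fail / n
        ll = _null_loglik(obs_het, obs_hom, n_blank, p, pn, beta)
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    ll_full = _null_loglik(obs_het, obs_hom, n_blank, p, pn, beta)

    # restricted model: no null allele; beta = blank fraction, p = observed
    p0 = {a: cnt[a] / tot for a in alleles}
    beta0 = n_blank / n
    ll_null = _null_loglik(obs_het, obs_hom, n_blank, p0, 0.0, beta0)
    lrt = max(2 * (ll_full - ll_null), 0.0)
    p_value = 0.5 * stats.chi2.sf(lrt, df=1) if lrt > 0 else 1.0

    if not converged:
        warnings.warn("null-allele EM did not converge")
    return NullAlleleFit(
        null_freq=float(pn),
        beta=float(beta),
        log_likelihood=float(ll_full),
        converged=converged,
        p_value=float(p_value),
        visible_freqs={a: float(v) for a, v in p.items()},
        n_iter=it,
    )


# ------------------------------------------------ index of association

def _pairwise_locus_distances(gt: GenotypeTable) -> np.ndarray:
    """(n_pairs, L) allelic mismatch counts (0, 1 or 2) per locus.
    Samples with any missing data are excluded beforehand by the caller."""
    geno = np.sort(gt.alleles, axis=2)  # (n, L, 2)
    n = gt.n_samples
    iu, ju = np.triu_indices(n, k=1)
    a_i, a_j = geno[iu], geno[ju]  # (np, L, 2)
    # multiset intersection of two sorted 2-element multisets is the best
    # of the direct and crossed copy-wise matchings
    direct = (a_i == a_j).sum(axis=2)
    cross = (a_i == a_j[:, :, ::-1]).sum(axis=2)
    shared = np.maximum(direct, cross)
    return (2 - shared).astype(float)


def index_of_association_rd(
    gt: GenotypeTable, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Standardized index of association r_bar_d over unique MLGs.

    r_bar_d = sum_{l<m} cov(d_l, d_m) / sum_{l<m} sqrt(var_l var_m) over
    per-locus pairwise-distance vectors.  The permutation null shuffles
    allele copies among individuals independently at each locus
    (one-sided, add-one corrected).  Samples with missing data are
    excluded before computing pair distances.
    """
    if gt.n_loci < 2:
        raise ValidationError("index of association needs at least 2 loci")
    complete = ~gt.missing.any(axis=1)
    sub = gt.subset(complete)
    if sub.n_samples < 3:
        raise ValidationError("need at least 3 complete samples")

    def rd_of(table: GenotypeTable) -> float:
        d = _pairwise_locus_distances(table)  # (np, L)
        cov = np.cov(d.T, ddof=1)
        var = np.diag(cov)
        iu = np.triu_indices(table.n_loci, k=1)
        denom = np.sum(np.sqrt(var[iu[0]] * var[iu[1]]))
        if denom <= 0:
            return np.nan
        return float(np.sum(cov[iu]) / denom)

    obs = rd_of(sub)
    if n_perm == 0:
        return obs, np.nan
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = sub.alleles.copy()
        for l in range(sub.n_loci):
            pool = rng.permutation(perm[:, l, :].ravel())
            perm[:, l, :] = pool.reshape(-1, 2)
        stat = rd_of(GenotypeTable(sub.sample_id, sub.site_id, sub.locus_names, perm))
        if not np.isnan(stat) and stat >= obs:
            hits += 1
    return obs, (hits + 1) / (n_perm + 1)


# ---------------------------------------------------- site summary table

def site_diversity_table(
    gt: GenotypeTable,
    partition: MLGPartition,
    rarefaction_g: tuple[int, ...] = (14, 20),
    n_perm: int = 999,
    seed: int = 0,
    psex_threshold: float = 0.05,
) -> pd.DataFrame:
    """Assemble the per-site diversity summary (Table-1-shaped).

    Diversity statistics are computed on clone-corrected data (unique MLGs
    per site); N, G, R and PID refer to the full ramet sample.  Rarefied
    richness columns are filled only for g values supported by every site.
    """
    cc = clone_correct(gt, partition)
    sites = gt.sites
    g_by_site = partition.g_by_site()
    max_group = partition.max_group_size_by_site()
    cc_by_site = {s: cc.by_site(s) for s in sites}

    rows = []
    for idx, site in enumerate(sites):
        full = gt.by_site(site)
        sub = cc_by_site[site]
        n, g = full.n_samples, g_by_site[site]
        r = clonal_richness(n, g) if n >= 2 else np.nan
        pid_l, pid_cum, pid_n = probability_of_identity(full)
        h_o, h_nb, f_is, f_p, _ = diversity_stats(sub, n_perm=n_perm, seed=seed + idx)
        n_alleles = sum(len(d) for d in allele_counts(sub))
        row = dict(
            site=site, N=n, G=g, R=r, nA=n_alleles,
            H_O=h_o, H_NB=h_nb, F_IS=f_is, F_IS_p=f_p,
            PID=pid_cum[-1], PID_N=pid_n, max_samples_per_MLG=max_group[site],
        )
        for g_std in rarefaction_g:
            ok = all(
                min(((~t.missing[:, l]).sum()) for l in range(t.n_loci)) >= g_std
                for t in cc_by_site.values() if t.n_samples > 0
            )
            if ok:
                row[f"A_R_{g_std}"] = rarefied_richness(sub, g_std)
                others = [cc_by_site[s] for s in sites if s != site and cc_by_site[s].n_samples > 0]
                row[f"P_A_{g_std}"] = rarefied_richness(sub, g_std, private=True, reference=others)
            else:
                row[f"A_R_{g_std}"] = np.nan
                row[f"P_A_{g_std}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
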