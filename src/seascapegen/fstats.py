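"""Genetic differentiation and its diagnostics.

Global and pairwise F_ST by Weir & Cockerham (1984) variance components
(with a GenAlEx-style AMOVA Phi_PT alternative), permutation tests, the
Rousset linearization F/(1-F), the per-locus G_ST vs H_S correlation used
to screen for mutation-driven downward bias in F_ST, individual-level
spatial autocorrelation over distance classes (Smouse & Peakall), and the
Evanno delta-K statistic on supplied clustering log-likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import DistanceMatrix, GenotypeTable, ValidationError

__all__ = [
    "FstResult",
    "AutocorrResult",
    "DeltaKResult",
    "GstHsResult",
    "weir_cockerham",
    "amova_phipt",
    "fst",
    "linearize_fst",
    "gst_hs_correlation",
    "spatial_autocorrelation",
    "evanno_delta_k",
]


# ------------------------------------------------------ Weir & Cockerham

def _wc_components(alleles: np.ndarray, missing: np.ndarray, labels: np.ndarray):
    """Per-locus Weir-Cockerham variance components (a, b, c) summed over
    alleles.  `alleles` is (n, L, 2); `labels` integer population codes."""
    n_loci = alleles.shape[1]
    pops = np.unique(labels)
    a_sum = np.zeros(n_loci)
    b_sum = np.zeros(n_loci)
    c_sum = np.zeros(n_loci)
    for l in range(n_loci):
        rows = ~missing[:, l]
        lab = labels[rows]
        g = alleles[rows, l, :]
        ns = np.array([(lab == p).sum() for p in pops], dtype=float)
        use = ns >= 1
        if use.sum() < 2:
            continue
        ns = ns[use]
        pops_l = pops[use]
        r = len(ns)
        nbar = ns.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        het = g[:, 0] != g[:, 1]
        for allele in np.unique(g):
            has = g == allele
            p_i = np.array([has[lab == p].sum() / (2 * (lab == p).sum()) for p in pops_l])
            h_i = np.array(
                [(het[lab == p] & has[lab == p].any(axis=1)).sum() / (lab == p).sum() for p in pops_l]
            )
            pbar = (ns * p_i).sum() / (r * nbar)
            s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (ns * h_i).sum() / (r * nbar)
            inner = pbar * (1 - pbar) - (r - 1) / r * s2
            a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            a_sum[l] += a
            b_sum[l] += b
            c_sum[l] += c
    return a_sum, b_sum, c_sum


def weir_cockerham(gt: GenotypeTable) -> tuple[float, float, float]:
    """Multi-locus Weir-Cockerham (theta, f, F_IT): variance components
    summed over alleles and loci before forming the ratios."""
    labels = pd.factorize(gt.site_id)[0]
    a, b, c = _wc_components(gt.alleles, gt.missing, labels)
    A, B, C = a.sum(), b.sum(), c.sum()
    theta = A / (A + B + C) if (A + B + C) != 0 else np.nan
    f = 1 - C / (B + C) if (B + C) != 0 else np.nan
    fit = 1 - C / (A + B + C) if (A + B + C) != 0 else np.nan
    return float(theta), float(f), float(fit)


def amova_phipt(gt: GenotypeTable) -> float:
    """GenAlEx-style Phi_PT: AMOVA on haploid-collapsed allele copies.

    Each allele copy is a haploid unit; squared distance between copies is
    0/1 identity.  Phi_PT = sigma2_among / (sigma2_among + sigma2_within).
    """
    labels = pd.factorize(gt.site_id)[0]
    pops = np.unique(labels)
    num = 0.0
    den = 0.0
    for l in range(gt.n_loci):
        rows = ~gt.missing[:, l]
        lab = np.repeat(labels[rows], 2)
        vals = gt.alleles[rows, l, :].ravel()
        N = len(vals)
        if N == 0:
            continue
        # sums of squared 0/1 distances: SS = (pairs) - (identical pairs)
        _, tot_counts = np.unique(vals, return_counts=True)
        ss_total = (N * (N - 1) / 2 - ((tot_counts * (tot_counts - 1)) / 2).sum()) / N
        ss_within = 0.0
        sizes = []
        for p in pops:
            v = vals[lab == p]
            if len(v) == 0:
                continue
            sizes.append(len(v))
            _, cts = np.unique(v, return_counts=True)
            ss_within += (len(v) * (len(v) - 1) / 2 - ((cts * (cts - 1)) / 2).sum()) / len(v)
        sizes = np.array(sizes, dtype=float)
        k = len(sizes)
        if k < 2:
            continue
        ss_among = ss_total - ss_within
        df_among = k - 1
        df_within = N - k
        ms_among = ss_among / df_among
        ms_within = ss_within / df_within if df_within > 0 else np.nan
        n0 = (N - (sizes**2).sum() / N) / df_among
        sigma_among = max((ms_among - ms_within) / n0, 0.0)
        num += sigma_among
        den += sigma_among + ms_within
    return float(num / den) if den > 0 else np.nan


@dataclass
class FstResult:
    global_theta: float
    global_p: float | None
    pairwise: DistanceMatrix
    pairwise_p: np.ndarray | None
    estimator: str
    n_perm: int
    seed: int
    excluded_sites: list[str] = field(default_factory=list)


def _estimate(gt: GenotypeTable, estimator: str) -> float:
    if estimator == "weir_cockerham":
        return weir_cockerham(gt)[0]
    if estimator == "amova":
        return amova_phipt(gt)
    raise ValueError("estimator must be 'weir_cockerham' or 'amova'")


def _perm_p(gt: GenotypeTable, estimator: str, obs: float, n_perm: int, rng) -> float:
    """Permute individuals across sites and recompute (add-one corrected)."""
    hits = 0
    labels = gt.site_id.copy()
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        stat = _estimate(GenotypeTable(gt.sample_id, perm, gt.locus_names, gt.alleles), estimator)
        if not np.isnan(stat) and stat >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def fst(
    gt: GenotypeTable,
    estimator: str = "weir_cockerham",
    n_perm: int = 999,
    seed: int = 0,
    pairwise_perm: bool = True,
) -> FstResult:
    """Global and pairwise F_ST with permutation tests.

    Input should be clone-corrected (unique MLGs).  Sites with fewer than
    2 samples are excluded with a warning.  The permutation unit is the
    individual: site labels are shuffled and the statistic recomputed;
    p is add-one corrected.  Set pairwise_perm=False to skip the per-pair
    tests (the pairwise estimates are still returned).
    """
    sites = gt.sites
    counts = {s: int((gt.site_id == s).sum()) for s in sites}
    keep = [s for s in sites if counts[s] >= 2]
    excluded = [s for s in sites if counts[s] < 2]
    if excluded:
        warnings.warn(f"sites excluded from F_ST (fewer than 2 samples): {excluded}")
    if len(keep) < 2:
        raise ValidationError("F_ST needs at least 2 sites with 2+ samples")
    sub = gt.subset(np.isin(gt.site_id, keep))

    rng = np.random.default_rng(seed)
    theta = _estimate(sub, estimator)
    global_p = _perm_p(sub, estimator, theta, n_perm, rng) if n_perm else None

    k = len(keep)
    pw = np.zeros((k, k))
    pw_p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            pair = sub.subset(np.isin(sub.site_id, [keep[i], keep[j]]))
            t = _estimate(pair, estimator)
            pw[i, j] = pw[j, i] = t
            if n_perm and pairwise_perm:
                p = _perm_p(pair, estimator, t, n_perm, rng)
                pw_p[i, j] = pw_p[j, i] = p
    # negative estimates are reported raw in the matrix; DistanceMatrix
    # requires nonnegative values, so store a clamped copy and keep the
    # raw matrix alongside
    pairwise = DistanceMatrix(site_ids=keep, values=np.maximum(pw, 0.0))
    result = FstResult(
        global_theta=float(theta),
        global_p=global_p,
        pairwise=pairwise,
        pairwise_p=pw_p if (n_perm and pairwise_perm) else None,
        estimator=estimator,
        n_perm=n_perm,
        seed=seed,
        excluded_sites=excluded,
    )
    result.pairwise_raw = pw  # unclamped values, may be slightly negative
    return result


def linearize_fst(values: np.ndarray | DistanceMatrix) -> np.ndarray | DistanceMatrix:
    """Rousset linearization F/(1-F); negative inputs clamped to 0 first."""
    if isinstance(values, DistanceMatrix):
        return DistanceMatrix(values.site_ids, linearize_fst(values.values))
    v = np.asarray(values, dtype=float)
    if (v >= 1).any():
        raise ValidationError("cannot linearize F_ST = 1 (infinite)")
    v = np.maximum(v, 0.0)
    return v / (1 - v)


# ------------------------------------------------------------- G_ST vs H_S

@dataclass
class GstHsResult:
    gst: np.ndarray  # per locus
    hs: np.ndarray  # per locus
    r_gh: float
    p: float
    n_boot: int


def gst_hs_correlation(gt: GenotypeTable, n_boot: int = 10000, seed: int = 0) -> GstHsResult:
    """Correlation of per-locus Nei G_ST with within-site diversity H_S.

    A significantly negative correlation indicates high-mutation loci
    dragging the multi-locus F_ST down; a positive / non-significant one
    indicates F_ST is not underestimated.  p is a two-sided bootstrap over
    loci.
    """
    if gt.n_loci < 3:
        raise ValidationError("need at least 3 loci")
    sites = gt.sites
    gst = np.empty(gt.n_loci)
    hs = np.empty(gt.n_loci)
    for l in range(gt.n_loci):
        per_site_h = []
        per_site_p = []
        for s in sites:
            sub = gt.by_site(s)
            rows = ~sub.missing[:, l]
            g = sub.alleles[rows, l, :]
            n = g.shape[0]
            if n < 2:
                continue
            _, cts = np.unique(g, return_counts=True)
            p = cts / (2 * n)
            h = (2 * n / (2 * n - 1)) * (1 - np.sum(p**2))
            per_site_h.append(h)
            per_site_p.append((np.unique(g, return_counts=True), n))
        hs[l] = np.mean(per_site_h)
        # H_T from unweighted mean allele frequencies across sites
        freq_maps = []
        for s in sites:
            sub = gt.by_site(s)
            rows = ~sub.missing[:, l]
            g = sub.alleles[rows, l, :]
            if g.shape[0] < 2:
                continue
            al, cts = np.unique(g, return_counts=True)
            freq_maps.append(dict(zip(al.tolist(), (cts / cts.sum()).tolist())))
        alleles = sorted({a for m in freq_maps for a in m})
        pbar = np.array([np.mean([m.get(a, 0.0) for m in freq_maps]) for a in alleles])
        ht = 1 - np.sum(pbar**2)
        gst[l] = (ht - hs[l]) / ht if ht > 0 else np.nan

    valid = ~np.isnan(gst)
    if valid.sum() < 3 or np.std(gst[valid]) == 0 or np.std(hs[valid]) == 0:
        raise ValidationError("G_ST / H_S variance degenerate across loci")
    r = float(np.corrcoef(gst[valid], hs[valid])[0, 1])

    if n_boot == 0:
        return GstHsResult(gst=gst, hs=hs, r_gh=r, p=np.nan, n_boot=0)
    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(valid)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.choice(idx, size=len(idx), replace=True)
        if np.std(gst[pick]) == 0 or np.std(hs[pick]) == 0:
            boots[b] = np.nan
            continue
        boots[b] = np.corrcoef(gst[pick], hs[pick])[0, 1]
    boots = boots[~np.isnan(boots)]
    nb = len(boots)
    # add-one correction keeps the bootstrap sign test away from exact 0
    p = 2 * min(((boots <= 0).sum() + 1) / (nb + 1), ((boots >= 0).sum() + 1) / (nb + 1))
    return GstHsResult(gst=gst, hs=hs, r_gh=r, p=float(min(p, 1.0)), n_boot=n_boot)


# ------------------------------------------- spatial autocorrelation

@dataclass
class AutocorrResult:
    endpoints_km: np.ndarray
    r: np.ndarray  # per class, NaN where undefined
    pair_counts: np.ndarray
    perm_low: np.ndarray
    perm_high: np.ndarray
    boot_low: np.ndarray
    boot_high: np.ndarray
    n_perm: int
    n_boot: int


def _genetic_covariance(gt: GenotypeTable) -> np.ndarray:
    """Double-centered covariance from Smouse-Peakall squared genetic
    distances (half the squared Euclidean distance between per-locus
    allele-count vectors, summed over loci).  Missing loci are imputed
    with twice the overall allele frequencies."""
    n = gt.n_samples
    blocks = []
    for l in range(gt.n_loci):
        rows = ~gt.missing[:, l]
        vals = gt.alleles[rows, l, :]
        alleles = np.unique(vals)
        counts = np.zeros((n, len(alleles)))
        for k, a in enumerate(alleles):
            counts[rows, k] = (gt.alleles[rows, l, :] == a).sum(axis=1)
        if (~rows).any() and rows.any():
            counts[~rows] = counts[rows].mean(axis=0)
        blocks.append(counts)
    X = np.hstack(blocks)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2) / 2.0
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ sq @ J


def _class_r(C: np.ndarray, members: np.ndarray) -> float:
    """Autocorrelation for one distance class: sum of between-pair
    covariances over the mean self-covariance of the paired individuals."""
    iu, ju = np.nonzero(members)
    if len(iu) < 2:  # fewer than 2 ordered entries => <1 pair
        return np.nan
    cxy = C[iu, ju].sum()
    cxx = ((np.diag(C)[iu] + np.diag(C)[ju]) / 2).sum()
    if cxx <= 0:
        return np.nan
    return float(cxy / cxx)


def spatial_autocorrelation(
    gt: GenotypeTable,
    coords: np.ndarray,
    class_endpoints_km: np.ndarray,
    n_perm: int = 9999,
    n_boot: int = 9999,
    seed: int = 0,
    crs: str = "planar",
) -> AutocorrResult:
    """Multivariate spatial autocorrelation of individual genotypes.

    Distance classes are half-open intervals (lower, upper] over the given
    endpoints (km), the first class starting at 0.  The permutation null
    shuffles individual locations; bootstrap CIs resample pairs within
    each class.
    """
    coords = np.asarray(coords, dtype=float)
    n = gt.n_samples
    if coords.shape != (n, 2):
        raise ValidationError("coords must be (n_samples, 2)")
    C = _genetic_covariance(gt)
    if crs == "lonlat":
        geo = _haversine_km(coords)
    else:
        geo = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)) / 1000.0

    ends = np.asarray(class_endpoints_km, dtype=float)
    lowers = np.concatenate([[0.0], ends[:-1]])
    off = ~np.eye(n, dtype=bool)
    memberships = [
        (geo > lo) & (geo <= hi) & off for lo, hi in zip(lowers, ends)
    ]
    r_obs = np.array([_class_r(C, m) for m in memberships])
    counts = np.array([int(m.sum() // 2) for m in memberships])

    rng = np.random.default_rng(seed)
    perm_lo = np.full(len(ends), np.nan)
    perm_hi = np.full(len(ends), np.nan)
    if n_perm:
        sims = np.full((n_perm, len(ends)), np.nan)
        for b in range(n_perm):
            order = rng.permutation(n)
            gperm = geo[np.ix_(order, order)]
            for k, (lo, hi) in enumerate(zip(lowers, ends)):
                m = (gperm > lo) & (gperm <= hi) & off
                sims[b, k] = _class_r(C, m)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            perm_lo = np.nanpercentile(sims, 2.5, axis=0)
            perm_hi = np.nanpercentile(sims, 97.5, axis=0)

    boot_lo = np.full(len(ends), np.nan)
    boot_hi = np.full(len(ends), np.nan)
    if n_boot:
        diag = np.diag(C)
        for k, m in enumerate(memberships):
            iu, ju = np.nonzero(np.triu(m))
            if len(iu) < 2:
                continue
            vals_xy = C[iu, ju]
            vals_xx = (diag[iu] + diag[ju]) / 2
            stats_b = np.empty(n_boot)
            for b in range(n_boot):
                pick = rng.integers(len(iu), size=len(iu))
                denom = vals_xx[pick].sum()
                stats_b[b] = vals_xy[pick].sum() / denom if denom > 0 else np.nan
            boot_lo[k] = np.nanpercentile(stats_b, 2.5)
            boot_hi[k] = np.nanpercentile(stats_b, 97.5)

    return AutocorrResult(
        endpoints_km=ends, r=r_obs, pair_counts=counts,
        perm_low=perm_lo, perm_high=perm_hi,
        boot_low=boot_lo, boot_high=boot_hi,
        n_perm=n_perm, n_boot=n_boot,
    )


def _haversine_km(coords: np.ndarray) -> np.ndarray:
    """Great-circle distances (km) between lon/lat degree coordinates."""
    lon = np.radians(coords[:, 0])
    lat = np.radians(coords[:, 1])
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


# ---------------------------------------------------------------- delta K

@dataclass
class DeltaKResult:
    k_values: np.ndarray
    mean_l: np.ndarray
    sd_l: np.ndarray
    delta_k: np.ndarray  # NaN at endpoints / undefined
    best_k: int | None


def evanno_delta_k(logl: pd.DataFrame | np.ndarray, k_values: np.ndarray | None = None) -> DeltaKResult:
    """Evanno second-difference statistic on clustering log-likelihoods.

    ``logl`` is runs x K (columns ordered by K).  delta_K(K) =
    |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)), defined only for
    interior K with positive run-to-run sd.
    """
    if isinstance(logl, pd.DataFrame):
        if k_values is None:
            k_values = np.array([int(c) for c in logl.columns])
        arr = logl.to_numpy(dtype=float)
    else:
        arr = np.asarray(logl, dtype=float)
        if k_values is None:
            k_values = np.arange(1, arr.shape[1] + 1)
    k_values = np.asarray(k_values)
    if arr.shape[1] < 3:
        raise ValidationError("delta-K needs at least 3 consecutive K values")
    if arr.shape[0] < 2:
        raise ValidationError("delta-K needs at least 2 runs per K")
    if not np.all(np.diff(k_values) == 1):
        raise ValidationError("K values must be consecutive")
    mean_l = arr.mean(axis=0)
    sd_l = arr.std(axis=0, ddof=1)
    dk = np.full(len(k_values), np.nan)
    for i in range(1, len(k_values) - 1):
        if sd_l[i] > 0:
            dk[i] = abs(mean_l[i + 1] - 2 * mean_l[i] + mean_l[i - 1]) / sd_l[i]
        else:
            warnings.warn(f"zero run-to-run sd at K={k_values[i]}; delta-K undefined there")
    best = None
    if np.isfinite(dk).any():
        best = int(k_values[np.nanargmax(dk)])
    return DeltaKResult(k_values=k_values, mean_l=mean_l, sd_l=sd_l, delta_k=dk, best_k=best)
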