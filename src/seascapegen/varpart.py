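"""The inference core: ordinations, matrix correlation, and partial-RDA
variance partitioning of genetic differentiation.

The response block GS is a PCoA embedding of linearized F_ST; the
predictor blocks are PCNM spatial eigenvectors of overwater distance
(GD), a PCA of connectivity-network metrics (OC, built in
`seascapegen.network`), and correspondence-analysis axes of the habitat
covariates (EN).  ``variation_partitioning`` decomposes the adjusted R^2
of "GS ~ GD + OC + EN" into marginal, conditional (unique), shared and
residual fractions with permutation F-tests (marginal tests permute
response rows; conditional tests permute reduced-model residuals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.sparse.csgraph import minimum_spanning_tree

from .types import DistanceMatrix, EnvironmentTable, ValidationError

__all__ = [
    "OrdinationResult",
    "VarpartResult",
    "gower",
    "mantel",
    "pcoa",
    "pcnm",
    "encode_environment",
    "correspondence_analysis",
    "rda",
    "variation_partitioning",
    "select_predictor_axes",
]


# ---------------------------------------------------------------- Gower

def gower(env: EnvironmentTable | pd.DataFrame) -> DistanceMatrix:
    """Gower dissimilarity over mixed-type habitat columns.

    Numeric columns contribute range-normalized absolute differences,
    categorical and boolean columns 0/1 mismatch; the dissimilarity is
    the average over non-missing columns.  Zero-range numeric columns are
    excluded with a warning.
    """
    if isinstance(env, EnvironmentTable):
        df = env.data
        numeric = list(EnvironmentTable.NUMERIC)
        categorical = list(EnvironmentTable.CATEGORICAL) + list(EnvironmentTable.BOOLEAN)
        ids = env.site_ids
    else:
        df = env
        numeric = [c for c in df.columns if c != "site_id" and pd.api.types.is_numeric_dtype(df[c]) and df[c].dtype != bool]
        categorical = [c for c in df.columns if c != "site_id" and c not in numeric]
        ids = df["site_id"].tolist() if "site_id" in df.columns else [str(i) for i in df.index]
    n = len(df)
    total = np.zeros((n, n))
    n_cols = 0
    for col in numeric:
        v = df[col].to_numpy(dtype=float)
        rng = v.max() - v.min()
        if rng == 0:
            warnings.warn(f"zero-range numeric column {col!r} excluded from Gower")
            continue
        total += np.abs(v[:, None] - v[None, :]) / rng
        n_cols += 1
    for col in categorical:
        v = df[col].to_numpy()
        total += (v[:, None] != v[None, :]).astype(float)
        n_cols += 1
    if n_cols == 0:
        raise ValidationError("no usable columns for Gower dissimilarity")
    return DistanceMatrix(site_ids=ids, values=total / n_cols)


# --------------------------------------------------------------- Mantel

def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel matrix correlation with a row/column permutation test.

    Pearson correlation of the off-diagonal upper triangles; one matrix's
    rows and columns are permuted jointly; p is add-one corrected.
    """
    if a.site_ids != b.site_ids:
        raise ValidationError("Mantel matrices must share site labels and order")
    n = len(a.site_ids)
    if n < 4:
        raise ValidationError("Mantel test needs at least 4 sites")
    va, vb = a.condensed(), b.condensed()
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValidationError("constant matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    if n_perm == 0:
        return r_obs, np.nan
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    B = b.values
    hits = 0
    for _ in range(n_perm):
        order = rng.permutation(n)
        vp = B[np.ix_(order, order)][iu]
        r = np.corrcoef(va, vp)[0, 1]
        if alternative == "greater":
            hits += r >= r_obs
        elif alternative == "two-sided":
            hits += abs(r) >= abs(r_obs)
        else:
            raise ValueError("alternative must be 'greater' or 'two-sided'")
    return r_obs, (hits + 1) / (n_perm + 1)


# ----------------------------------------------------------------- PCoA

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # site x retained axes
    eigenvalues: np.ndarray  # all axes, descending
    variance_share: np.ndarray  # over positive eigenvalues
    n_positive: int


def pcoa(d: DistanceMatrix, eig_tol: float = 1e-8) -> OrdinationResult:
    """Principal coordinate analysis (metric MDS) of a distance matrix.

    Double-centers -1/2 J D^2 J, eigen-decomposes, and retains axes with
    eigenvalue > eig_tol * max eigenvalue; coordinates are eigenvectors
    scaled by sqrt(eigenvalue).
    """
    D = d.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals[0] <= 0:
        raise ValidationError("no positive eigenvalue: degenerate distance matrix")
    pos = vals > eig_tol * vals[0]
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    share = vals[pos] / vals[pos].sum()
    frame = pd.DataFrame(
        coords, index=pd.Index(d.site_ids, name="site_id"),
        columns=[f"PCo{i + 1}" for i in range(pos.sum())],
    )
    return OrdinationResult(
        coordinates=frame, eigenvalues=vals, variance_share=share, n_positive=int(pos.sum())
    )


# ----------------------------------------------------------------- PCNM

def pcnm(
    d_geo: DistanceMatrix,
    truncation: float | None = None,
    eig_tol: float = 1e-8,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates of neighbour matrices: spatial eigenvectors.

    Distances above the truncation threshold t are replaced by 4t (t
    defaults to the longest minimum-spanning-tree edge); positive-
    eigenvalue eigenvectors of the truncated matrix's PCoA are returned
    as spatial predictors, with their eigenvalues.
    """
    n = len(d_geo.site_ids)
    if n < 3:
        raise ValidationError("PCNM needs at least 3 sites")
    D = d_geo.values.copy()
    if truncation is None:
        mst = minimum_spanning_tree(D).toarray()
        truncation = float(mst.max())
    trunc = D.copy()
    over = trunc > truncation
    np.fill_diagonal(over, False)
    trunc[over] = 4 * truncation
    res = pcoa(DistanceMatrix(d_geo.site_ids, trunc), eig_tol=eig_tol)
    # unit-norm eigenvectors as predictors
    coords = res.coordinates.to_numpy()
    eigvals = res.eigenvalues[: res.n_positive]
    vectors = coords / np.sqrt(eigvals)
    frame = pd.DataFrame(
        vectors, index=pd.Index(d_geo.site_ids, name="site_id"),
        columns=[f"PCNM{i + 1}" for i in range(vectors.shape[1])],
    )
    return frame, eigvals


# ------------------------------------------------- correspondence analysis

def encode_environment(env: EnvironmentTable) -> pd.DataFrame:
    """One-hot categorical/boolean columns; range-scale numeric columns to
    [0, 1] so they enter the CA as abundance-like columns."""
    df = env.data
    out = {}
    for col in EnvironmentTable.CATEGORICAL:
        for level in sorted(df[col].unique()):
            out[f"{col}={level}"] = (df[col] == level).to_numpy(dtype=float)
    for col in EnvironmentTable.BOOLEAN:
        yes = df[col].to_numpy(dtype=float)
        out[f"{col}=yes"] = yes
        out[f"{col}=no"] = 1.0 - yes
    for col in EnvironmentTable.NUMERIC:
        v = df[col].to_numpy(dtype=float)
        rng = v.max() - v.min()
        out[col] = (v - v.min()) / rng if rng > 0 else np.zeros(len(v))
    return pd.DataFrame(out, index=pd.Index(env.site_ids, name="site_id"))


def correspondence_analysis(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Correspondence analysis of a nonnegative table.

    SVD of the standardized residuals of the row/column profile matrix;
    returns row (site) principal coordinates and per-axis inertia shares.
    """
    N = table.to_numpy(dtype=float)
    if (N < 0).any():
        raise ValidationError("CA table must be nonnegative")
    if (N.sum(axis=1) == 0).any() or (N.sum(axis=0) == 0).any():
        raise ValidationError("CA table has an all-zero row or column")
    P = N / N.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    inertia = sv**2
    if inertia.sum() <= 1e-12:
        raise ValidationError("zero total inertia: table rows are identical profiles")
    keep = inertia > 1e-12 * inertia[0]
    U, sv = U[:, keep], sv[keep]
    row_scores = (U * sv) / np.sqrt(r)[:, None]
    share = inertia[keep] / inertia.sum()
    frame = pd.DataFrame(
        row_scores, index=table.index, columns=[f"CA{i + 1}" for i in range(row_scores.shape[1])]
    )
    return frame, share


# ------------------------------------------------------------------- RDA

def _as_matrix(x) -> np.ndarray:
    arr = x.to_numpy(dtype=float) if hasattr(x, "to_numpy") else np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _drop_collinear(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """QR-based removal of linearly dependent columns (warns)."""
    if X.shape[1] == 0:
        return X
    Q, R, piv = qr(X, pivoting=True, mode="economic")
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * (diag[0] if diag[0] > 0 else 1)).sum())
    if rank < X.shape[1]:
        warnings.warn(f"dropping {X.shape[1] - rank} collinear predictor column(s)")
        keep = np.sort(piv[:rank])
        return X[:, keep]
    return X


def _fit_r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Fraction of total variance of Y captured by OLS on X (both already
    centered); returns (R^2, rank of X)."""
    if X.shape[1] == 0:
        return 0.0, 0
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ coef
    tot = (Y**2).sum()
    if tot <= 0:
        raise ValidationError("response matrix has zero variance")
    return float((fitted**2).sum() / tot), int(rank)


def _adjust(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment 1 - (1 - R^2)(n - 1)/(n - m - 1)."""
    if n - m - 1 <= 0:
        return np.nan
    return 1 - (1 - r2) * (n - 1) / (n - m - 1)


@dataclass
class RdaResult:
    r2: float
    adj_r2: float
    f: float
    p: float | None
    df_model: int
    df_residual: int
    n_perm: int


def rda(
    y,
    x,
    z=None,
    n_perm: int = 999,
    seed: int = 0,
) -> RdaResult:
    """(Partial) redundancy analysis of response matrix y on predictors x,
    optionally conditioning on z.

    Without z: R^2 is the variance fraction of (column-centered) y
    captured by the fitted values on x; F = (R^2/m) / ((1-R^2)/(n-m-1));
    the permutation test shuffles rows of y.  With z: y and x are first
    residualized on z; R^2 is reported as a fraction of the *original*
    response variance (the semipartial form used in variance
    partitioning), F uses the full-model residual, and permutations follow
    Freedman-Lane (reduced-model residuals are shuffled).
    """
    Y = _as_matrix(y)
    X = _drop_collinear(_as_matrix(x))
    n = Y.shape[0]
    Y = Y - Y.mean(axis=0)
    X = X - X.mean(axis=0)
    rng = np.random.default_rng(seed)

    if z is None:
        r2, m = _fit_r2(Y, X)
        if n <= m + 1:
            raise ValidationError("too few rows for the predictor count")
        df_res = n - m - 1
        f_obs = (r2 / m) / ((1 - r2) / df_res) if m else np.nan
        p = None
        if n_perm:
            hits = 0
            for _ in range(n_perm):
                Yp = Y[rng.permutation(n)]
                r2p, _ = _fit_r2(Yp, X)
                fp = (r2p / m) / ((1 - r2p) / df_res)
                if fp >= f_obs:
                    hits += 1
            p = (hits + 1) / (n_perm + 1)
        return RdaResult(r2, _adjust(r2, n, m), float(f_obs), p, m, df_res, n_perm)

    Z = _drop_collinear(_as_matrix(z))
    Z = Z - Z.mean(axis=0)
    coef_z, _, mz, _ = np.linalg.lstsq(Z, Y, rcond=None)
    Y_fit_z = Z @ coef_z
    Y_res = Y - Y_fit_z
    coef_xz, _, _, _ = np.linalg.lstsq(Z, X, rcond=None)
    X_res = X - Z @ coef_xz
    X_res = _drop_collinear(X_res)
    m = np.linalg.matrix_rank(X_res)
    tot = (Y**2).sum()

    def semipartial_f(Yr: np.ndarray) -> tuple[float, float]:
        coef, _, _, _ = np.linalg.lstsq(X_res, Yr, rcond=None)
        fitted = X_res @ coef
        ss_x = (fitted**2).sum()
        ss_res_full = (Yr**2).sum() - ss_x
        r2_semi = ss_x / tot
        df_res = n - 1 - m - mz
        if df_res <= 0:
            raise ValidationError("too few rows for conditioning + predictors")
        f_stat = (ss_x / m) / (ss_res_full / df_res)
        return r2_semi, f_stat

    r2, f_obs = semipartial_f(Y_res)
    df_res = n - 1 - m - mz
    p = None
    if n_perm:
        hits = 0
        for _ in range(n_perm):
            Y_star = Y_fit_z + Y_res[rng.permutation(n)]
            Y_star = Y_star - Y_star.mean(axis=0)
            coef_s, _, _, _ = np.linalg.lstsq(Z, Y_star, rcond=None)
            Yr_s = Y_star - Z @ coef_s
            _, f_p = semipartial_f(Yr_s)
            if f_p >= f_obs:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    return RdaResult(float(r2), np.nan, float(f_obs), p, m, df_res, n_perm)


# ------------------------------------------------- variance partitioning

@dataclass
class VarpartResult:
    """Adjusted-R^2 decomposition of GS ~ GD + OC + EN (Table-2 shape)."""

    block_names: list[str]
    marginal: pd.DataFrame  # per block: adj_r2, r2, df_mod, df_res, F, p
    conditional: pd.DataFrame  # unique fractions, same columns
    union_adj_r2: dict[str, float]  # adjusted R^2 of all 7 predictor unions
    union_r2: dict[str, float]
    residual_adj: float
    n: int = 0

    def fractions(self, adjusted: bool = True) -> dict[str, float]:
        """The seven unique/shared fractions plus the residual.

        Keys: each block name (unique fraction), "name1&name2" (pairwise
        shared), "&".join(all) (triple shared), "residual".  On the
        unadjusted scale the fractions sum to 1 exactly.
        """
        u = self.union_adj_r2 if adjusted else self.union_r2
        a, b, c = self.block_names
        T = u[f"{a}+{b}+{c}"]
        ua = T - u[f"{b}+{c}"]
        ub = T - u[f"{a}+{c}"]
        uc = T - u[f"{a}+{b}"]
        g = u[a] + u[b] + u[c] - u[f"{a}+{b}"] - u[f"{a}+{c}"] - u[f"{b}+{c}"] + T
        d_ab = u[a] + u[b] - u[f"{a}+{b}"] - g
        d_ac = u[a] + u[c] - u[f"{a}+{c}"] - g
        d_bc = u[b] + u[c] - u[f"{b}+{c}"] - g
        return {
            a: ua, b: ub, c: uc,
            f"{a}&{b}": d_ab, f"{a}&{c}": d_ac, f"{b}&{c}": d_bc,
            f"{a}&{b}&{c}": g,
            "residual": 1 - T,
        }

    def table(self) -> pd.DataFrame:
        """Marginal + conditional rows with adjusted R^2 in percent."""
        rows = []
        for name, row in self.marginal.iterrows():
            rows.append(["Marginal", name, 100 * row.adj_r2, row.df_mod, row.df_res, row.F, row.p])
        rows.append(["Marginal", "Residual", 100 * self.residual_adj, np.nan, np.nan, np.nan, np.nan])
        for name, row in self.conditional.iterrows():
            others = " + ".join(b for b in self.block_names if b != name)
            rows.append(["Conditional", f"{name}|({others})", 100 * row.adj_r2, row.df_mod, row.df_res, row.F, row.p])
        return pd.DataFrame(rows, columns=["effect", "term", "R2_adj_pct", "df_mod", "df_res", "F", "p"])


def variation_partitioning(
    y,
    blocks: dict[str, "pd.DataFrame | np.ndarray"],
    n_perm: int = 999,
    seed: int = 0,
) -> VarpartResult:
    """Partition the variance of y over three predictor blocks.

    Computes R^2 and adjusted R^2 for all 7 nonempty block unions;
    marginal fraction of block i = adj R^2(i); unique (conditional)
    fraction = adj R^2(all) - adj R^2(other two); shared fractions by
    inclusion-exclusion; residual = 1 - adj R^2(all).  Permutation
    F-tests as in :func:`rda`.
    """
    names = list(blocks)
    if len(names) != 3:
        raise ValidationError("variation partitioning expects exactly 3 blocks")
    Y = _as_matrix(y)
    n = Y.shape[0]
    mats = {k: _as_matrix(v) for k, v in blocks.items()}

    union_r2: dict[str, float] = {}
    union_adj: dict[str, float] = {}
    Yc = Y - Y.mean(axis=0)
    for k in range(1, 4):
        for combo in combinations(names, k):
            X = np.hstack([mats[c] for c in combo])
            X = _drop_collinear(X - X.mean(axis=0))
            r2, m = _fit_r2(Yc, X)
            key = "+".join(combo)
            union_r2[key] = r2
            union_adj[key] = _adjust(r2, n, m)

    rng = np.random.default_rng(seed)
    marg_rows = []
    cond_rows = []
    for i, name in enumerate(names):
        others = [b for b in names if b != name]
        res_m = rda(Y, mats[name], n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        marg_rows.append(
            dict(block=name, adj_r2=union_adj[name], r2=union_r2[name],
                 df_mod=res_m.df_model, df_res=res_m.df_residual, F=res_m.f, p=res_m.p)
        )
        res_c = rda(
            Y, mats[name], z=np.hstack([mats[o] for o in others]),
            n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
        )
        unique_adj = union_adj["+".join(names)] - union_adj["+".join(others)]
        cond_rows.append(
            dict(block=name, adj_r2=unique_adj, r2=res_c.r2,
                 df_mod=res_c.df_model, df_res=res_c.df_residual, F=res_c.f, p=res_c.p)
        )

    marginal = pd.DataFrame(marg_rows).set_index("block")
    conditional = pd.DataFrame(cond_rows).set_index("block")
    all_key = "+".join(names)
    return VarpartResult(
        block_names=names,
        marginal=marginal,
        conditional=conditional,
        union_adj_r2=union_adj,
        union_r2=union_r2,
        residual_adj=float(1 - union_adj[all_key]),
        n=n,
    )


# ------------------------------------------------------ axis selection

def select_predictor_axes(
    candidates: pd.DataFrame,
    gs: pd.DataFrame,
    rule: str = "first_k",
    k: int = 3,
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Choose predictor axes: the first k (default 3), or screen out
    candidates whose maximum absolute correlation with any GS axis
    reaches ``threshold`` (retaining the rest)."""
    if rule == "first_k":
        if k > candidates.shape[1]:
            raise ValidationError(f"k={k} exceeds {candidates.shape[1]} candidate axes")
        return candidates.iloc[:, :k]
    if rule == "correlation_screen":
        G = _as_matrix(gs)
        G = (G - G.mean(axis=0)) / np.where(G.std(axis=0) > 0, G.std(axis=0), 1.0)
        keep = []
        for col in candidates.columns:
            v = candidates[col].to_numpy(dtype=float)
            sd = v.std()
            if sd == 0:
                continue
            vz = (v - v.mean()) / sd
            max_r = np.max(np.abs(vz @ G / len(vz)))
            if max_r < threshold:
                keep.append(col)
        return candidates[keep]
    raise ValueError("rule must be 'first_k' or 'correlation_screen'")
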