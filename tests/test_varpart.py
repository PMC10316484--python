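"""Ordinations, Mantel tests, RDA and variance partitioning.

Independent oracles: scikit-bio for Mantel and PCoA, R vegan (via
Rscript) for adjusted R^2 of the partitioned models, plus closed-form and
constructed fixtures.
"""

import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from seascapegen import varpart as vp
from seascapegen.types import DistanceMatrix, EnvironmentTable, ValidationError


def dmat(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"S{i}" for i in range(len(values))]
    return DistanceMatrix(site_ids=ids, values=values)


def random_distance(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return dmat(d)


# ----------------------------------------------------------------- Gower


class TestGower:
    def test_hand_computed_mixed_pair(self):
        df = pd.DataFrame(
            {"site_id": ["A", "B"], "depth": [0.0, 5.0], "sediment": ["sand", "sand"]}
        )
        d = vp.gower(df)
        assert d.values[0, 1] == pytest.approx(0.5)  # (1 + 0) / 2

    def test_identical_rows_zero(self, env_table):
        env2 = EnvironmentTable(data=pd.concat([env_table.data.iloc[[0]]] * 2).assign(
            site_id=["A", "B"]).reset_index(drop=True))
        assert vp.gower(env2).values[0, 1] == 0.0

    def test_maximal_difference_is_one(self):
        df = pd.DataFrame(
            {"site_id": ["A", "B"], "depth": [0.0, 5.0], "sediment": ["sand", "silt"],
             "habitat": ["reef terrace", "reef lagoon"]}
        )
        assert vp.gower(df).values[0, 1] == pytest.approx(1.0)

    def test_zero_range_column_excluded(self):
        df = pd.DataFrame({"site_id": ["A", "B"], "depth": [2.0, 2.0], "sediment": ["sand", "silt"]})
        with pytest.warns(UserWarning, match="zero-range"):
            d = vp.gower(df)
        assert d.values[0, 1] == pytest.approx(1.0)  # only the mismatch column


# ---------------------------------------------------------------- Mantel


class TestMantel:
    def test_identity_gives_r_one_small_p(self):
        a = random_distance(10, 0)
        r, p = vp.mantel(a, a, n_perm=199, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_antimonotone_gives_minus_one(self):
        a = random_distance(8, 1)
        b_vals = a.values.max() - a.values
        np.fill_diagonal(b_vals, 0.0)
        b = dmat(b_vals, ids=a.site_ids)
        r, _ = vp.mantel(a, b, n_perm=0)
        assert r == pytest.approx(-1.0)

    def test_agrees_with_skbio_oracle(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM, mantel as skbio_mantel

        a, b = random_distance(12, 3), random_distance(12, 4)
        r_ours, _ = vp.mantel(a, b, n_perm=0)
        r_skbio, _, _ = skbio_mantel(SkbioDM(a.values), SkbioDM(b.values), permutations=0)
        assert r_ours == pytest.approx(float(r_skbio), abs=1e-12)

    def test_relabeling_invariance(self):
        a, b = random_distance(9, 5), random_distance(9, 6)
        order = np.random.default_rng(7).permutation(9)
        a2 = dmat(a.values[np.ix_(order, order)], ids=[a.site_ids[i] for i in order])
        b2 = dmat(b.values[np.ix_(order, order)], ids=[b.site_ids[i] for i in order])
        assert vp.mantel(a, b, 0)[0] == pytest.approx(vp.mantel(a2, b2, 0)[0], abs=1e-12)

    def test_constant_matrix_rejected(self):
        ones = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValidationError, match="constant"):
            vp.mantel(dmat(ones), random_distance(5, 8), 0)


# ------------------------------------------------------------------ PCoA


class TestPcoa:
    def test_equilateral_triangle_eigenvalues(self):
        d = dmat(np.ones((3, 3)) - np.eye(3))
        res = vp.pcoa(d)
        assert res.n_positive == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        assert abs(res.eigenvalues[2]) < 1e-12

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(9, 2))
        d_in = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = vp.pcoa(dmat(d_in))
        coords = res.coordinates.to_numpy()
        d_out = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        assert np.allclose(d_out, d_in, atol=1e-10)

    def test_agrees_with_skbio_oracle(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        d = random_distance(8, 9)
        ours = vp.pcoa(d)
        theirs = skbio_pcoa(d.values, number_of_dimensions=ours.n_positive)
        assert np.allclose(
            np.sort(ours.eigenvalues[: ours.n_positive]),
            np.sort(theirs.eigvals.to_numpy()[: ours.n_positive]),
            atol=1e-8,
        )

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            vp.pcoa(dmat(np.zeros((4, 4))))


# ------------------------------------------------------------------ PCNM


class TestPcnm:
    def test_transect_axes_resemble_cosines(self):
        x = np.arange(10, dtype=float)
        d = dmat(np.abs(x[:, None] - x[None, :]))
        axes, eig = vp.pcnm(d)
        # first axis of a 1-D transect is a half-cosine: monotone signs
        first = axes.iloc[:, 0].to_numpy()
        sign_changes = np.sum(np.diff(np.sign(first)) != 0)
        assert sign_changes == 1
        # later axes oscillate faster
        later = axes.iloc[:, min(2, axes.shape[1] - 1)].to_numpy()
        assert np.sum(np.diff(np.sign(later)) != 0) > sign_changes

    def test_inert_truncation_equals_plain_pcoa(self):
        d = random_distance(7, 11)
        axes, eig = vp.pcnm(d, truncation=d.values.max() + 1)
        ref = vp.pcoa(d)
        vecs = ref.coordinates.to_numpy() / np.sqrt(ref.eigenvalues[: ref.n_positive])
        assert np.allclose(np.abs(axes.to_numpy()), np.abs(vecs), atol=1e-10)

    def test_rank_bound(self):
        d = random_distance(6, 12)
        axes, _ = vp.pcnm(d)
        assert axes.shape[1] <= 5

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValidationError):
            vp.pcnm(random_distance(2, 0))


# ------------------------------------------- correspondence analysis


class TestCorrespondenceAnalysis:
    def test_block_diagonal_first_axis_separates(self):
        table = pd.DataFrame(
            [[5, 4, 0, 0], [4, 5, 0, 0], [0, 0, 5, 4], [0, 0, 4, 5]],
            index=["A", "B", "C", "D"], columns=list("wxyz"),
        )
        scores, share = vp.correspondence_analysis(table)
        first = scores.iloc[:, 0].to_numpy()
        assert np.sign(first[0]) == np.sign(first[1]) != np.sign(first[2])
        # oracle: direct SVD of the standardized residuals
        N = table.to_numpy(float); P = N / N.sum()
        r, c = P.sum(1), P.sum(0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        sv = np.linalg.svd(S, compute_uv=False)
        assert share[0] == pytest.approx(sv[0] ** 2 / (sv**2).sum())

    def test_uniform_table_zero_inertia_rejected(self):
        table = pd.DataFrame(np.ones((4, 3)), columns=list("abc"))
        with pytest.raises(ValidationError, match="inertia"):
            vp.correspondence_analysis(table)

    def test_axes_orthogonal_in_chi_square_metric(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.integers(1, 10, size=(8, 5)).astype(float))
        scores, _ = vp.correspondence_analysis(table)
        N = table.to_numpy(); r = N.sum(1) / N.sum()
        F = scores.to_numpy()
        G = (F * r[:, None]).T @ F
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-10

    def test_environment_encoding_shapes(self, env_table):
        enc = vp.encode_environment(env_table)
        assert (enc.to_numpy() >= 0).all()
        assert {"depth", "n_other_seagrass"} <= set(enc.columns)
        assert any(c.startswith("sediment=") for c in enc.columns)


# ------------------------------------------------------------------- RDA


def make_blocks(n=24, seed=0, collinear=False):
    rng = np.random.default_rng(seed)
    X1 = rng.normal(size=(n, 2))
    X2 = X1 + 1e-9 * rng.normal(size=(n, 2)) if collinear else rng.normal(size=(n, 2))
    X3 = rng.normal(size=(n, 2))
    return X1, X2, X3


class TestRda:
    def test_exact_linear_response_r2_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        Y = X @ rng.normal(size=(3, 2))
        res = vp.rda(Y, X, n_perm=0)
        assert res.r2 == pytest.approx(1.0)
        assert res.adj_r2 == pytest.approx(1.0)

    def test_matches_ols_oracle_single_predictor(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 1))
        Y = rng.normal(size=(30, 3))
        res = vp.rda(Y, x, n_perm=0)
        # oracle: per-column squared correlation aggregated by variance
        Yc = Y - Y.mean(0)
        xc = (x - x.mean()).ravel()
        ss_tot = (Yc**2).sum()
        ss_exp = sum(
            (np.dot(xc, Yc[:, j]) ** 2) / np.dot(xc, xc) for j in range(Y.shape[1])
        )
        assert res.r2 == pytest.approx(ss_exp / ss_tot, abs=1e-12)

    def test_orthogonal_predictor_null_p(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(25, 2))
        X = rng.normal(size=(25, 2))
        res = vp.rda(Y, X, n_perm=199, seed=4)
        assert res.r2 < 0.3
        assert res.p > 0.01

    def test_signal_share_recovery(self):
        rng = np.random.default_rng(5)
        n = 200
        X = rng.normal(size=(n, 3))
        signal = X @ rng.normal(size=(3, 2))
        signal /= signal.std()
        noise = rng.normal(size=(n, 2))
        s = 0.6
        Y = np.sqrt(s) * signal + np.sqrt(1 - s) * noise
        res = vp.rda(Y, X, n_perm=0)
        assert abs(res.adj_r2 - s) < 0.05

    def test_collinear_columns_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(15, 2))
        X = np.hstack([x, x[:, :1] * 2.0])
        with pytest.warns(UserWarning, match="collinear"):
            res = vp.rda(rng.normal(size=(15, 2)), X, n_perm=0)
        assert res.df_model == 2


class TestVariationPartitioning:
    def test_unadjusted_fractions_sum_to_one(self):
        X1, X2, X3 = make_blocks(seed=7)
        rng = np.random.default_rng(8)
        Y = X1 @ rng.normal(size=(2, 2)) + rng.normal(size=(24, 2))
        res = vp.variation_partitioning(Y, {"A": X1, "B": X2, "C": X3}, n_perm=0)
        fr = res.fractions(adjusted=False)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_blocks_shared_near_zero(self):
        rng = np.random.default_rng(9)
        n = 60
        M = rng.normal(size=(n, 6))
        M -= M.mean(axis=0)
        Q = np.linalg.qr(M)[0]  # exactly orthogonal centered columns
        X1, X2, X3 = Q[:, :2], Q[:, 2:4], Q[:, 4:6]
        Y = X1 @ rng.normal(size=(2, 2)) + X2 @ rng.normal(size=(2, 2)) + 0.5 * rng.normal(size=(n, 2))
        res = vp.variation_partitioning(Y, {"A": X1, "B": X2, "C": X3}, n_perm=0)
        fr = res.fractions()
        for key in ("A&B", "A&C", "B&C", "A&B&C"):
            assert abs(fr[key]) < 0.08
        # conditional ~ marginal for the informative blocks
        assert abs(res.conditional.loc["A", "adj_r2"] - res.marginal.loc["A", "adj_r2"]) < 0.08

    def test_duplicated_block_moves_to_shared(self):
        rng = np.random.default_rng(10)
        n = 40
        X1 = rng.normal(size=(n, 2))
        X2 = X1.copy()
        X3 = rng.normal(size=(n, 2))
        Y = X1 @ rng.normal(size=(2, 2)) + 0.3 * rng.normal(size=(n, 2))
        with pytest.warns(UserWarning, match="collinear"):
            res = vp.variation_partitioning(Y, {"A": X1, "B": X2, "C": X3}, n_perm=0)
        assert abs(res.conditional.loc["A", "adj_r2"]) < 0.05
        assert abs(res.conditional.loc["B", "adj_r2"]) < 0.05
        assert res.marginal.loc["A", "adj_r2"] == pytest.approx(res.marginal.loc["B", "adj_r2"], abs=1e-10)

    def test_agrees_with_vegan_oracle(self, tmp_path):
        """Adjusted R^2 of every predictor union matches R vegan."""
        rng = np.random.default_rng(11)
        n = 14
        X1, X2, X3 = rng.normal(size=(3, n, 2))
        Y = X1 @ rng.normal(size=(2, 3)) + X3 @ rng.normal(size=(2, 3)) + rng.normal(size=(n, 3))
        for name, arr in (("Y", Y), ("X1", X1), ("X2", X2), ("X3", X3)):
            pd.DataFrame(arr).to_csv(tmp_path / f"{name}.csv", index=False)
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            args <- commandArgs(trailingOnly=TRUE)
            dir <- args[1]
            Y <- as.matrix(read.csv(file.path(dir, "Y.csv")))
            X1 <- as.matrix(read.csv(file.path(dir, "X1.csv")))
            X2 <- as.matrix(read.csv(file.path(dir, "X2.csv")))
            X3 <- as.matrix(read.csv(file.path(dir, "X3.csv")))
            adj <- function(...) RsquareAdj(rda(Y, cbind(...)))$adj.r.squared
            out <- c(adj(X1), adj(X2), adj(X3), adj(X1,X2), adj(X1,X3), adj(X2,X3), adj(X1,X2,X3))
            cat(paste(sprintf("%.12f", out), collapse=","))
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        proc = subprocess.run(
            ["Rscript", str(tmp_path / "oracle.R"), str(tmp_path)],
            capture_output=True, text=True, timeout=300,
        )
        assert proc.returncode == 0, proc.stderr
        vegan_vals = [float(v) for v in proc.stdout.strip().split(",")]
        res = vp.variation_partitioning(Y, {"A": X1, "B": X2, "C": X3}, n_perm=0)
        keys = ["A", "B", "C", "A+B", "A+C", "B+C", "A+B+C"]
        ours = [res.union_adj_r2[k] for k in keys]
        assert np.allclose(ours, vegan_vals, atol=1e-9)


class TestSelectPredictorAxes:
    def test_first_k_identity_when_k_all(self):
        df = pd.DataFrame(np.eye(4), columns=list("abcd"))
        out = vp.select_predictor_axes(df, df, rule="first_k", k=4)
        pd.testing.assert_frame_equal(out, df)

    def test_zero_threshold_screens_everything(self):
        rng = np.random.default_rng(12)
        cand = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        gs = pd.DataFrame(rng.normal(size=(10, 2)))
        out = vp.select_predictor_axes(cand, gs, rule="correlation_screen", threshold=0.0)
        assert out.shape[1] == 0

    def test_screen_reproduces_hand_ranked_subset(self):
        rng = np.random.default_rng(13)
        n = 50
        g = rng.normal(size=n)
        gs = pd.DataFrame({"PCo1": g})
        cand = pd.DataFrame(
            {
                "aligned": g + 0.01 * rng.normal(size=n),  # |r| ~ 1 -> screened out
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        out = vp.select_predictor_axes(cand, gs, rule="correlation_screen", threshold=0.7)
        assert list(out.columns) == ["noise1", "noise2"]

    def test_k_beyond_candidates_errors(self):
        df = pd.DataFrame(np.eye(3))
        with pytest.raises(ValidationError):
            vp.select_predictor_axes(df, df, k=5)
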