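import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from karstpheno import ordination_stats as ordn
from karstpheno.ordination_stats import (
    cca_ptv,
    correspondence_analysis,
    dca,
    envfit_vectors,
    modified_permutation_test,
    spearman_statistic,
    spearman_table,
)


def reciprocal_averaging_axis1(arr, n_iter=5000, seed=0):
    """Independent power-iteration oracle for the first CA axis."""
    P = arr / arr.sum()
    r, c = P.sum(1), P.sum(0)
    rng = np.random.default_rng(seed)
    x = rng.normal(size=len(r))
    x -= np.average(x, weights=r)
    lam = np.nan
    for _ in range(n_iter):
        u = (P.T @ x) / c
        x = (P @ u) / r
        x -= np.average(x, weights=r)
        lam = np.sqrt(np.sum(r * x**2))
        x /= lam
    return x, lam


class TestCA:
    def test_matches_reciprocal_averaging_oracle(self, small_matrix):
        res = correspondence_analysis(small_matrix)
        x, lam = reciprocal_averaging_axis1(small_matrix.to_numpy())
        assert abs(lam - res.eigenvalues[0]) < 1e-8
        s1 = res.site_scores.to_numpy()[:, 0]
        assert np.allclose(np.abs(x), np.abs(s1), atol=1e-8)

    def test_disconnected_blocks_give_unit_eigenvalue(self):
        arr = np.block(
            [[np.ones((3, 2)), np.zeros((3, 2))], [np.zeros((3, 2)), np.ones((3, 2))]]
        )
        M = pd.DataFrame(arr, index=[f"p{i}" for i in range(6)], columns=list("wxyz"))
        res = correspondence_analysis(M)
        assert abs(res.eigenvalues[0] - 1.0) < 1e-10

    def test_plot_permutation_equivariance(self, small_matrix):
        res = correspondence_analysis(small_matrix)
        perm = [3, 0, 5, 1, 4, 2]
        permuted = small_matrix.iloc[perm]
        res2 = correspondence_analysis(permuted)
        np.testing.assert_allclose(
            res2.site_scores.to_numpy(),
            res.site_scores.iloc[perm].to_numpy(),
            atol=1e-10,
        )

    def test_zero_row_named_in_error(self, small_matrix):
        bad = small_matrix.copy()
        bad.loc["p2"] = 0.0
        with pytest.raises(ValueError, match="p2"):
            correspondence_analysis(bad)

    def test_eigenvalues_at_most_one(self, default_analysis):
        res = correspondence_analysis(default_analysis["analysis"].data)
        assert res.eigenvalues.max() <= 1 + 1e-10

    def test_matches_vegan_eigenvalues(self, small_matrix, tmp_path):
        """Cross-check against the R vegan implementation."""
        small_matrix.to_csv(tmp_path / "m.csv", index=False)
        script = (
            'suppressMessages(library(vegan));'
            f'M <- as.matrix(read.csv("{tmp_path}/m.csv"));'
            'cat(sprintf("%.15g", head(cca(M)$CA$eig, 3)), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = np.array([float(v) for v in out.stdout.split()])
        res = correspondence_analysis(small_matrix)
        np.testing.assert_allclose(res.eigenvalues[:3], ref, atol=1e-8)


class TestDCA:
    def test_detrending_off_reduces_to_ca(self, small_matrix):
        ca = correspondence_analysis(small_matrix)
        d = dca(small_matrix, detrend=False, rescaling=False)
        np.testing.assert_allclose(
            d.site_scores.to_numpy(), ca.site_scores.to_numpy()[:, : d.site_scores.shape[1]]
        )
        np.testing.assert_allclose(d.eigenvalues, ca.eigenvalues[: len(d.eigenvalues)])

    def test_axis1_eigenvalue_unchanged_by_detrending(self, default_analysis):
        M = default_analysis["analysis"].data
        ca = correspondence_analysis(M)
        d = dca(M, n_axes=2, rescaling=False)
        assert abs(d.eigenvalues[0] - ca.eigenvalues[0]) < 1e-12

    def test_segment_means_of_axis2_vanish_along_axis1(self, default_analysis):
        M = default_analysis["analysis"].data
        n_segments = 26
        d = dca(M, n_segments=n_segments, n_axes=2, rescaling=False)
        arr = M.to_numpy()
        r = arr.sum(axis=1) / arr.sum()
        z = d.site_scores.to_numpy()[:, 0]
        x = d.site_scores.to_numpy()[:, 1]
        width = (z.max() - z.min()) / n_segments
        seg = np.clip(((z - z.min()) / width).astype(int), 0, n_segments - 1)
        for s in np.unique(seg):
            m = seg == s
            assert abs(np.average(x[m], weights=r[m])) < 1e-6

    def test_rescaling_only_scales_axes(self, small_matrix):
        plain = dca(small_matrix, rescaling=False, n_axes=2)
        scaled = dca(small_matrix, rescaling=True, n_axes=2)
        for j in range(2):
            a = plain.site_scores.to_numpy()[:, j]
            b = scaled.site_scores.to_numpy()[:, j]
            ratio = b[np.abs(a) > 1e-12] / a[np.abs(a) > 1e-12]
            np.testing.assert_allclose(ratio, ratio[0], rtol=1e-8)

    def test_bad_segment_count_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="segments"):
            dca(small_matrix, n_segments=1)


class TestEnvfit:
    def scores(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, 2)), index=[f"p{i}" for i in range(n)], columns=["axis1", "axis2"]
        )

    def test_variable_equal_to_axis1_is_perfect_fit(self):
        sc = self.scores()
        v = pd.DataFrame({"x": sc["axis1"]})
        out = envfit_vectors(sc, v)
        assert out.loc["x", "r"] > 1 - 1e-10
        assert abs(abs(out.loc["x", "dx"]) - 1) < 1e-8
        assert abs(out.loc["x", "dy"]) < 1e-8

    def test_r2_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        sc = self.scores(seed=3)
        v = pd.DataFrame({"x": rng.normal(size=40)}, index=sc.index)
        out = envfit_vectors(sc, v)
        X = np.column_stack([np.ones(40), sc.to_numpy()])
        y = v["x"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert abs(out.loc["x", "r"] ** 2 - r2) < 1e-10

    def test_topographic_mode_emits_parametric_p_only(self):
        sc = self.scores()
        rng = np.random.default_rng(1)
        v = pd.DataFrame({"depth": rng.normal(size=40)}, index=sc.index)
        out = envfit_vectors(sc, v, modes={"depth": "topographic"})
        assert np.isfinite(out.loc["depth", "p_par"])
        assert np.isnan(out.loc["depth", "p_perm"])
        assert np.isnan(out.loc["depth", "p_modif"])

    def test_constant_variable_rejected(self):
        sc = self.scores()
        v = pd.DataFrame({"x": np.ones(40)}, index=sc.index)
        with pytest.raises(ValueError, match="constant"):
            envfit_vectors(sc, v)

    def test_direction_has_unit_norm(self):
        sc = self.scores(seed=9)
        rng = np.random.default_rng(9)
        v = pd.DataFrame({"x": sc["axis1"] * 0.3 + rng.normal(size=40)}, index=sc.index)
        out = envfit_vectors(sc, v)
        assert abs(np.hypot(out.loc["x", "dx"], out.loc["x", "dy"]) - 1) < 1e-12


class TestSpearman:
    def test_monotone_pairs(self):
        y = np.arange(10.0)
        stat = spearman_statistic(y)
        assert abs(stat(y[:, None])[0] - 1) < 1e-12
        assert abs(stat(y[::-1][:, None])[0] + 1) < 1e-12

    def test_ties_match_scipy_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(6, 25))
            x = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 5, size=n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            ref = stats.spearmanr(x, y).statistic
            got = spearman_statistic(y)(x[:, None])[0]
            assert abs(got - ref) < 1e-12

    def test_table_structure_and_applicability(self, default_sim, default_analysis):
        from karstpheno import traits as tm

        meta = default_sim["meta"]
        spectra = tm.flowering_spectrum(default_analysis["percent"], default_sim["traits"])
        eiv = tm.mean_eiv(default_analysis["percent"], default_sim["traits"])
        onset = tm.recode_onset(default_sim["traits"]["onset"])
        table = spearman_table(
            spectra[["March", "June", "n_onset"]],
            meta[["depth", "svf"]],
            eiv[["M", "L"]],
            presence=default_analysis["percent"].presence(),
            onset=onset,
            n_perm=49,
            seed=0,
        )
        topo = table[table["variable"] == "depth"]
        assert topo["p_perm"].isna().all() and topo["p_modif"].isna().all()
        deriv = table[table["variable"] == "M"]
        assert deriv["p_perm"].notna().all() and deriv["p_modif"].notna().all()
        march_depth = table.query("month == 'March' and variable == 'depth'")["r"].iloc[0]
        assert march_depth > 0.3


class TestModifiedPermutation:
    def presence(self, n_plots=30, n_sp=20, seed=0):
        rng = np.random.default_rng(seed)
        pres = rng.random((n_plots, n_sp)) > 0.5
        pres[:, 0] = True
        return pd.DataFrame(
            pres, index=[f"p{i}" for i in range(n_plots)], columns=[f"s{j}" for j in range(n_sp)]
        )

    def test_nperm_zero_rejected(self):
        pres = self.presence()
        attr = pd.Series(np.arange(20.0), index=pres.columns)
        with pytest.raises(ValueError, match="n_perm"):
            modified_permutation_test(pres, attr, spearman_statistic(np.arange(30.0)), n_perm=0)

    def test_constant_attribute_rejected(self):
        pres = self.presence()
        attr = pd.Series(np.ones(20), index=pres.columns)
        with pytest.raises(ValueError, match="constant"):
            modified_permutation_test(pres, attr, spearman_statistic(np.arange(30.0)), n_perm=9)

    def test_extreme_structure_reaches_minimal_p(self):
        # gradient plots, species sorted along it, attribute = niche position
        n_plots, n_sp = 40, 30
        pres = np.zeros((n_plots, n_sp), dtype=bool)
        for i in range(n_plots):
            j = int(i / n_plots * n_sp)
            pres[i, max(0, j - 3) : j + 3] = True
        pres_df = pd.DataFrame(
            pres, index=[f"p{i}" for i in range(n_plots)], columns=[f"s{j}" for j in range(n_sp)]
        )
        attr = pd.Series(np.arange(n_sp, dtype=float), index=pres_df.columns)
        gradient = np.arange(n_plots, dtype=float)
        p, t = modified_permutation_test(
            pres_df, attr, spearman_statistic(gradient), n_perm=199, seed=1
        )
        assert t > 0.95
        assert p == 1 / 200

    def test_reproducible_given_seed(self):
        pres = self.presence(seed=2)
        rng = np.random.default_rng(3)
        attr = pd.Series(rng.normal(size=20), index=pres.columns)
        stat = spearman_statistic(rng.normal(size=30))
        p1, _ = modified_permutation_test(pres, attr, stat, n_perm=99, seed=7)
        p2, _ = modified_permutation_test(pres, attr, stat, n_perm=99, seed=7)
        assert p1 == p2


class TestCCA:
    def test_inertia_conservation_and_dense_oracle(self):
        rng = np.random.default_rng(8)
        M = pd.DataFrame(rng.poisson(4.0, size=(12, 8)).astype(float) + 0.25)
        M.index = [f"p{i}" for i in range(12)]
        v = pd.Series(rng.normal(size=12), index=M.index)
        res = cca_ptv(M, v, n_perm=49, seed=0)
        # conservation: residual inertia computed independently
        arr = M.to_numpy()
        P = arr / arr.sum()
        r, c = P.sum(1), P.sum(0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        z = (np.sqrt(r) * (v.to_numpy() - r @ v.to_numpy()))[:, None]
        Q, _ = np.linalg.qr(z)
        resid = S - Q @ (Q.T @ S)
        assert abs(res.constrained_inertia + (resid**2).sum() - res.total_inertia) < 1e-10
        # dense eigen oracle: constrained inertia = sum of eigenvalues of the fitted part
        fitted = Q @ (Q.T @ S)
        eig = np.linalg.eigvalsh(fitted @ fitted.T)
        assert abs(res.constrained_inertia - eig.sum()) < 1e-10
        assert abs(res.ptv - 100 * res.constrained_inertia / res.total_inertia) < 1e-12

    def test_matches_vegan(self, small_matrix, tmp_path):
        rng = np.random.default_rng(4)
        v = pd.Series(rng.normal(size=6), index=small_matrix.index)
        small_matrix.to_csv(tmp_path / "m.csv", index=False)
        v.to_csv(tmp_path / "v.csv", index=False, header=False)
        script = (
            'suppressMessages(library(vegan));'
            f'M <- as.matrix(read.csv("{tmp_path}/m.csv"));'
            f'v <- scan("{tmp_path}/v.csv", quiet=TRUE);'
            "fit <- cca(M ~ v);"
            'cat(sprintf("%.15g", c(fit$CCA$tot.chi, fit$tot.chi)), sep="\\n")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
        con_ref, tot_ref = (float(s) for s in out.stdout.split())
        res = cca_ptv(small_matrix, v, n_perm=9, seed=0)
        assert abs(res.constrained_inertia - con_ref) < 1e-8
        assert abs(res.total_inertia - tot_ref) < 1e-8

    def test_constant_variable_rejected(self, small_matrix):
        v = pd.Series(np.ones(6), index=small_matrix.index)
        with pytest.raises(ValueError, match="constant"):
            cca_ptv(small_matrix, v)

    def test_permutation_p_on_grid_and_reproducible(self, small_matrix):
        rng = np.random.default_rng(5)
        v = pd.Series(rng.normal(size=6), index=small_matrix.index)
        res1 = cca_ptv(small_matrix, v, n_perm=99, seed=3)
        res2 = cca_ptv(small_matrix, v, n_perm=99, seed=3)
        assert res1.p_value == res2.p_value
        assert abs(res1.p_value * 100 - round(res1.p_value * 100)) < 1e-9
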