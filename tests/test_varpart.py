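"""FAMD, management clustering, stepwise selection and variance partitioning."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from soilscape import varpart as vp


def orthonormal_columns(n, k, rng):
    """Exactly orthogonal centered unit-variance columns."""
    X = rng.standard_normal((n, k + 1))
    X = X - X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    Q = Q[:, 1:k + 1]
    Q = Q - Q.mean(axis=0)
    return Q / Q.std(axis=0, ddof=1)


class TestFAMD:
    def test_pure_quantitative_equals_pca(self, rng):
        q = pd.DataFrame(rng.standard_normal((50, 4)), columns=list("abcd"))
        res = vp.famd(q, None)
        qs = (q - q.mean()) / q.std(ddof=0)
        U, s, _ = np.linalg.svd(qs.to_numpy(), full_matrices=False)
        np.testing.assert_allclose(np.abs(res.scores.to_numpy()),
                                   np.abs(U * s), atol=1e-8)

    def test_balanced_binary_category_symmetric_first_axis(self):
        cat = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10})
        res = vp.famd(None, cat)
        f1 = res.scores["F1"].to_numpy()
        assert np.allclose(f1[:10], f1[0])
        assert np.allclose(f1[10:], -f1[0])

    def test_component_variances_match_eigen_oracle(self, rng):
        quant = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("xyz"))
        cat = pd.DataFrame({
            "c1": rng.choice(["u", "v"], 40),
            "c2": rng.choice(["p", "q", "r"], 40),
            "c3": rng.choice(["m", "n"], 40),
        })
        res = vp.famd(quant, cat)
        # independent route: eigenvalues of the covariance of the processed matrix
        n = 40
        qs = ((quant - quant.mean()) / quant.std(ddof=0)).to_numpy()
        blocks = [qs]
        for col in cat.columns:
            d = pd.get_dummies(cat[col]).to_numpy(float)
            Z = d / np.sqrt(d.mean(axis=0))
            blocks.append(Z - Z.mean(axis=0))
        X = np.concatenate(blocks, axis=1)
        eig = np.sort(np.linalg.eigvalsh(X.T @ X / (n - 1)))[::-1]
        k = len(res.explained_variance)
        np.testing.assert_allclose(res.explained_variance, eig[:k], atol=1e-8)

    def test_empty_level_dropped_with_warning(self):
        cat = pd.DataFrame({"g": pd.Categorical(["a", "b", "a", "b"],
                                                categories=["a", "b", "c"])})
        with pytest.warns(UserWarning, match="empty levels"):
            res = vp.famd(None, cat)
        assert "g=c" not in res.columns


class TestClustering:
    def test_two_blobs_perfect_recovery(self, rng):
        scores = pd.DataFrame(np.vstack([
            rng.normal(0, 0.1, (20, 2)),
            rng.normal(5, 0.1, (20, 2)),
        ]))
        cl = vp.cluster_management(scores, k=2)
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, cl.labels) == 1.0

    def test_k_one_single_label(self, rng):
        cl = vp.cluster_management(pd.DataFrame(rng.standard_normal((10, 2))),
                                   k=1)
        assert cl.labels.nunique() == 1

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            vp.cluster_management(pd.DataFrame(rng.standard_normal((5, 2))),
                                  k=9)

    def test_six_management_clusters_recovered(self):
        # mimic the discriminating design: land cover x tillage x catch crop
        combos = [("forest", "none", "no"), ("crop", "perennial", "no"),
                  ("crop", "min", "yes"), ("crop", "min", "no"),
                  ("crop", "conv", "no"), ("crop", "hoe", "no")]
        sizes = (44, 7, 22, 57, 104, 33)
        aris = []
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            rows, truth = [], []
            for g, (combo, size) in enumerate(zip(combos, sizes)):
                for _ in range(size):
                    rows.append(combo)
                    truth.append(g)
            cat = pd.DataFrame(rows, columns=["land", "till", "catch"])
            quant = pd.DataFrame({
                "tfi": rng.normal(2, 0.4, len(cat)),        # not discriminating
                "rotation": rng.normal(3, 0.5, len(cat)),
            })
            res = vp.famd(quant, cat)
            cl = vp.cluster_management(res.scores, k=6, n_components=5)
            aris.append(adjusted_rand_score(truth, cl.labels))
        assert np.mean(aris) > 0.9

    def test_automatic_k_finds_well_separated_count(self, rng):
        centers = np.array([[0, 0], [8, 0], [0, 8]])
        pts = np.vstack([rng.normal(c, 0.3, (25, 2)) for c in centers])
        cl = vp.cluster_management(pd.DataFrame(pts))
        assert cl.k == 3


class TestAdjustedR2:
    def test_formula_example(self, rng):
        # engineer R^2 = 0.5 exactly at n=11, p=1
        n = 11
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std(ddof=1)
        e = rng.standard_normal(n)
        e = e - e.mean()
        e = e - x * (x @ e) / (x @ x)       # exactly orthogonal to x
        e = e / np.linalg.norm(e) * np.linalg.norm(x)  # equal SS
        y = x + e                            # R^2 = 1/2
        got = vp.adjusted_r2(y, pd.DataFrame({"x": x}))
        assert got == pytest.approx(1 - 0.5 * 10 / 9, abs=1e-10)

    def test_intercept_only_zero(self, rng):
        assert vp.adjusted_r2(rng.standard_normal(20), None) == 0.0

    def test_matches_brute_force_on_orthonormal_predictors(self, rng):
        n, k = 40, 3
        Q = orthonormal_columns(n, k, rng)
        y = rng.standard_normal(n)
        got = vp.adjusted_r2(y, Q)
        yc = y - y.mean()
        r2 = sum((Q[:, j] @ yc) ** 2 / (Q[:, j] @ Q[:, j])
                 for j in range(k)) / (yc @ yc)
        assert got == pytest.approx(1 - (1 - r2) * (n - 1) / (n - k - 1),
                                    abs=1e-10)

    def test_undefined_when_saturated(self, rng):
        with pytest.raises(ValueError, match="undefined"):
            vp.adjusted_r2(rng.standard_normal(4),
                           rng.standard_normal((4, 3)))


class TestForwardSelect:
    def test_true_predictor_selected(self):
        hits = 0
        for rep in range(40):
            rng = np.random.default_rng(rep)
            n = 120
            x1 = rng.standard_normal(n)
            noise_col = rng.standard_normal(n)
            y = 2 * x1 + rng.standard_normal(n)
            sel = vp.forward_select(y, pd.DataFrame({"x1": x1,
                                                     "junk": noise_col}),
                                    alpha=0.01)
            if sel == ["x1"]:
                hits += 1
        assert hits >= 38  # >= 95%

    def test_null_mostly_empty_with_alpha_guard(self):
        empties = 0
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            n = 278
            X = pd.DataFrame(rng.standard_normal((n, 5)),
                             columns=[f"c{i}" for i in range(5)])
            y = rng.standard_normal(n)
            if vp.forward_select(y, X, alpha=0.01) == []:
                empties += 1
        assert empties >= 45  # >= 90%

    def test_duplicate_column_selected_once(self, rng):
        n = 100
        x = rng.standard_normal(n)
        y = x + 0.1 * rng.standard_normal(n)
        X = pd.DataFrame({"a": x, "b": x.copy()})
        sel = vp.forward_select(y, X)
        assert sel == ["a"]

    def test_never_selects_zero_partial_correlation(self, rng):
        n = 60
        x = rng.standard_normal(n)
        y = 3 * x
        sel = vp.forward_select(y, pd.DataFrame({"x": x, "x2": 2 * x}))
        assert sel == ["x"]  # second is collinear, zero partial correlation


class TestSpatialSelection:
    def _pcnm(self, rng, n=278, k=20):
        return pd.DataFrame(orthonormal_columns(n, k, rng),
                            columns=[f"PCNM{i + 1}" for i in range(k)])

    def test_environment_explains_all_no_pcnm_selected(self):
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            n = 278
            env = pd.DataFrame({"e": rng.standard_normal(n)})
            y = 2 * env["e"].to_numpy() + 0.5 * rng.standard_normal(n)
            sel = vp.select_spatial_from_residuals(y, env, self._pcnm(rng),
                                                   alpha=0.01)
            if sel == []:
                wins += 1
        assert wins >= 18  # >= 90%

    def test_structured_residual_selects_right_vector(self):
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(500 + rep)
            n = 278
            pcnm = self._pcnm(rng)
            env = pd.DataFrame({"e": rng.standard_normal(n)})
            y = env["e"].to_numpy() + 0.6 * pcnm["PCNM3"].to_numpy() \
                + 0.5 * rng.standard_normal(n)
            sel = vp.select_spatial_from_residuals(y, env, pcnm, alpha=0.01)
            if "PCNM3" in sel:
                wins += 1
        assert wins >= 18  # >= 90%

    def test_zero_residual_empty_selection(self, rng):
        n = 50
        env = pd.DataFrame({"e": rng.standard_normal(n)})
        y = 3.0 * env["e"].to_numpy()
        sel = vp.select_spatial_from_residuals(y, env, self._pcnm(rng, n, 5))
        assert sel == []


class TestVariancePartition:
    def test_orthogonal_sets_unique_equals_marginal(self, rng):
        n = 100
        Q = orthonormal_columns(n, 3, rng)
        soil = pd.DataFrame({"s": Q[:, 0]})
        mgmt = pd.DataFrame({"m": Q[:, 1]})
        space = pd.DataFrame({"p": Q[:, 2]})
        y = 2 * Q[:, 0] + 1 * Q[:, 1] + 0.5 * Q[:, 2] \
            + 0.1 * rng.standard_normal(n)
        res = vp.variance_partition(y, soil, mgmt, space)
        for name, X in (("soil", soil), ("management", mgmt), ("space", space)):
            marginal = vp.adjusted_r2(y, X)
            assert res.fractions[name] == pytest.approx(marginal, abs=0.02)
        shared = sum(res.fractions[k] for k in res.fractions
                     if "_" in k)
        assert abs(shared) < 0.05

    def test_perfect_confounding_moves_variance_to_shared(self, rng):
        n = 80
        x = rng.standard_normal(n)
        y = x + 0.2 * rng.standard_normal(n)
        soil = pd.DataFrame({"s": x})
        mgmt = pd.DataFrame({"m": x.copy()})
        res = vp.variance_partition(y, soil, mgmt, None)
        assert abs(res.fractions["soil"]) < 0.02
        assert abs(res.fractions["management"]) < 0.02
        assert res.fractions["soil_management"] > 0.8

    def test_inclusion_exclusion_sums_exactly(self, rng):
        n = 60
        res = vp.variance_partition(
            rng.standard_normal(n),
            pd.DataFrame(rng.standard_normal((n, 2))),
            pd.DataFrame(rng.standard_normal((n, 3))),
            pd.DataFrame(rng.standard_normal((n, 2))))
        assert sum(res.fractions.values()) == pytest.approx(res.total,
                                                            abs=1e-10)

    def test_two_empty_sets_reduce_to_adjusted_r2(self, rng):
        n = 50
        soil = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"])
        y = soil["a"].to_numpy() + rng.standard_normal(n)
        with pytest.warns(UserWarning, match="empty"):
            res = vp.variance_partition(y, soil, None, None)
        assert res.fractions["soil"] == pytest.approx(vp.adjusted_r2(y, soil),
                                                      abs=1e-12)
        assert res.total == pytest.approx(vp.adjusted_r2(y, soil), abs=1e-12)

    def test_agrees_with_vegan_varpart(self, rng, tmp_path):
        # independent oracle: vegan::varpart in R on the same small dataset
        n = 40
        y = rng.standard_normal(n)
        X1 = rng.standard_normal((n, 2))
        X2 = rng.standard_normal((n, 2))
        X3 = rng.standard_normal((n, 1))
        res = vp.variance_partition(y, pd.DataFrame(X1), pd.DataFrame(X2),
                                    pd.DataFrame(X3))
        df = pd.DataFrame(np.column_stack([y, X1, X2, X3]),
                          columns=["y", "s1", "s2", "m1", "m2", "p1"])
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            d <- read.csv("{csv}")
            v <- varpart(d$y, ~ s1 + s2, ~ m1 + m2, ~ p1, data = d)
            f <- v$part$indfract$Adj.R.square
            cat(paste(f, collapse = ","))
        """)
        try:
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, timeout=300, check=True)
        except (FileNotFoundError, subprocess.CalledProcessError) as exc:
            pytest.fail(f"vegan oracle unavailable: {exc}")
        vals = [float(v) for v in out.stdout.strip().split(",")]
        # vegan order: [a]=X1, [b]=X2, [c]=X3, [d]=X1&X2, [e]=X2&X3,
        #              [f]=X1&X3, [g]=all
        assert res.fractions["soil"] == pytest.approx(vals[0], abs=1e-6)
        assert res.fractions["management"] == pytest.approx(vals[1], abs=1e-6)
        assert res.fractions["space"] == pytest.approx(vals[2], abs=1e-6)
        assert res.fractions["soil_management"] == pytest.approx(vals[3],
                                                                 abs=1e-6)
        assert res.fractions["management_space"] == pytest.approx(vals[4],
                                                                  abs=1e-6)
        assert res.fractions["soil_space"] == pytest.approx(vals[5], abs=1e-6)
        assert res.fractions["soil_management_space"] == pytest.approx(
            vals[6], abs=1e-6)


class TestPermuteMarginal:
    def test_minimum_p_is_one_over_nperm_plus_one(self, rng):
        n = 80
        x = rng.standard_normal(n)
        y = 5 * x + 0.1 * rng.standard_normal(n)
        p = vp.permute_marginal(y, soil=pd.DataFrame({"x": x}),
                                n_perm=99, seed=0)
        assert p["soil"] == pytest.approx(1 / 100)

    def test_p_values_invariant_to_affine_response(self, rng):
        n = 60
        soil = pd.DataFrame(rng.standard_normal((n, 2)))
        space = pd.DataFrame(rng.standard_normal((n, 2)))
        y = soil.iloc[:, 0].to_numpy() + rng.standard_normal(n)
        p1 = vp.permute_marginal(y, soil=soil, space=space, n_perm=49, seed=3)
        p2 = vp.permute_marginal(-2.0 * y + 7.0, soil=soil, space=space,
                                 n_perm=49, seed=3)
        assert p1 == p2

    def test_true_effect_detected_with_power(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            n = 278
            soil = pd.DataFrame({"s": rng.standard_normal(n)})
            space = pd.DataFrame({"p": rng.standard_normal(n)})
            # space contributes ~0.1 of variance
            y = soil["s"].to_numpy() + np.sqrt(0.25) * space["p"].to_numpy() \
                + np.sqrt(1.0) * rng.standard_normal(n)
            p = vp.permute_marginal(y, soil=soil, space=space, n_perm=199,
                                    seed=rep)
            if p["space"] < 0.01:
                hits += 1
        assert hits >= 18  # >= 90%
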