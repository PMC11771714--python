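"""Canonical correlation (vs brute-force eigen oracle) and per-day PCA."""

import numpy as np
import pandas as pd
import pytest

import npqdyn as nd
from npqdyn.multivariate import CanonicalCorrelation, pca_by_day, run_cca

PARAMS = ["a_qe", "tau_qe", "a_qm", "tau_qm", "a_qi", "max_npq"]


def eigen_oracle(X, Y):
    """Canonical correlations from the eigenvalues of
    Sxx^-1 Sxy Syy^-1 Syx — independent of the QR/SVD route."""
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    Sxx, Syy, Sxy = Xs.T @ Xs, Ys.T @ Ys, Xs.T @ Ys
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    ev = np.sort(np.linalg.eigvals(M).real)[::-1]
    return np.sqrt(np.clip(ev, 0.0, 1.0))


class TestCanonicalCorrelation:
    def test_matches_eigen_oracle_to_1e10(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 6))
        Y = X @ rng.standard_normal((6, 6)) + 0.7 * rng.standard_normal((80, 6))
        cca = CanonicalCorrelation().fit(X, Y)
        oracle = eigen_oracle(X, Y)[: len(cca.correlations_)]
        np.testing.assert_allclose(cca.correlations_, oracle, atol=1e-10)

    def test_exact_linear_transform_gives_correlation_one(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 6))
        Y = X @ rng.standard_normal((6, 5))
        cca = CanonicalCorrelation().fit(X, Y)
        assert np.isclose(cca.correlations_[0], 1.0, atol=1e-10)

    def test_correlations_sorted_and_bounded(self):
        rng = np.random.default_rng(2)
        X, Y = rng.standard_normal((60, 5)), rng.standard_normal((60, 4))
        c = CanonicalCorrelation().fit(X, Y).correlations_
        assert np.all(c[:-1] >= c[1:] - 1e-12)
        assert np.all((c >= 0) & (c <= 1))

    def test_affine_invariance_within_blocks(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((70, 4))
        Y = X[:, :2] @ rng.standard_normal((2, 3)) + rng.standard_normal((70, 3))
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        B = rng.standard_normal((3, 3)) + 4 * np.eye(3)
        a = CanonicalCorrelation().fit(X, Y).correlations_
        b = CanonicalCorrelation().fit(X @ A + 5.0, Y @ B - 2.0).correlations_
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_null_wilks_calibration(self):
        """Independent blocks: axis-1 Wilks p rejects at ~alpha."""
        rej = 0
        n = 200
        for seed in range(n):
            rng = np.random.default_rng(seed)
            X, Y = rng.standard_normal((500, 4)), rng.standard_normal((500, 4))
            cca = CanonicalCorrelation().fit(X, Y)
            rej += cca.wilks_.loc[1, "p"] < 0.05
        assert 0.03 <= rej / n <= 0.07

    def test_rank_deficient_block_warns_and_drops(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # rank 3 in 4 columns
        Y = rng.standard_normal((40, 3))
        with pytest.warns(UserWarning, match="rank"):
            cca = CanonicalCorrelation().fit(X, Y)
        assert len(cca.correlations_) == 3

    def test_needs_enough_rows(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            CanonicalCorrelation().fit(rng.standard_normal((8, 5)), rng.standard_normal((8, 5)))


class TestRunCCA:
    def _pheno(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.standard_normal((n, 6)), columns=PARAMS)
        for c in ["morning_Ta", "morning_VPD", "Fsd_3day", "VPD_3day"]:
            df[c] = rng.standard_normal(n)
        df["group"] = rng.choice(["elite", "diverse", "PI"], n)
        df["date"] = rng.choice(["2021-07-01", "2021-07-10"], n)
        return df

    def test_excludes_morning_ta_by_default(self):
        df = self._pheno()
        res = run_cca(df, PARAMS, ["morning_Ta", "morning_VPD", "Fsd_3day", "VPD_3day"])
        assert "morning_Ta" not in res.y_loadings.index
        assert "morning_VPD" in res.y_loadings.index

    def test_centroids_for_ordination(self):
        df = self._pheno()
        res = run_cca(
            df, PARAMS, ["morning_VPD", "Fsd_3day", "VPD_3day"], group_col="group", day_col="date"
        )
        assert res.centroids is not None
        assert set(res.centroids["group"]) == {"elite", "diverse", "PI"}
        assert len(res.centroids) == 6


class TestPCAByDay:
    def _pheno(self, seed=0, offset_param=None, offset=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in [f"G{i}" for i in range(12)] + ["RC"]:
            group = "RC" if g == "RC" else ("elite" if int(g[1:]) < 6 else "PI")
            for plot in range(4):
                vals = dict(zip(PARAMS, rng.standard_normal(6) * 0.1 + 1.0))
                if offset_param and group == "PI":
                    vals[offset_param] += offset
                rows.append({"genotype": g, "group": group, "date": "2021-07-01", **vals})
        return pd.DataFrame(rows)

    def test_collinear_data_pc1_explains_all(self):
        df = self._pheno()
        t = np.linspace(0, 1, len(df))
        for i, c in enumerate(PARAMS):
            df[c] = (i + 1) * t
        res = pca_by_day(df, "2021-07-01", PARAMS)
        assert res.explained_variance_ratio[0] > 0.999

    def test_group_offset_detected_on_loading_pc(self):
        df = self._pheno(offset_param="a_qe", offset=0.6)
        res = pca_by_day(df, "2021-07-01", PARAMS)
        lead = res.loadings.abs().idxmax(axis=0)
        pcs_with_aqe = [pc for pc in lead.index if lead[pc] == "a_qe"]
        assert pcs_with_aqe
        assert (res.group_anova_p[pcs_with_aqe] < 0.01).any()

    def test_scores_match_svd_oracle_up_to_sign(self):
        df = self._pheno()
        res = pca_by_day(df, "2021-07-01", PARAMS, n_components=2)
        X = df[PARAMS].to_numpy()
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        U, s, Vt = np.linalg.svd(Xs - Xs.mean(0), full_matrices=False)
        oracle = U[:, :2] * s[:2]
        for j in range(2):
            col = res.scores.iloc[:, j].to_numpy()
            assert np.allclose(col, oracle[:, j], atol=1e-8) or np.allclose(col, -oracle[:, j], atol=1e-8)

    def test_outlier_labels_beyond_z(self):
        df = self._pheno()
        df.loc[df["genotype"] == "G3", PARAMS] += 3.0
        res = pca_by_day(df, "2021-07-01", PARAMS)
        assert "G3" in set(res.outliers["genotype"])

    def test_needs_three_genotypes(self):
        df = self._pheno()
        with pytest.raises(ValueError):
            pca_by_day(df[df["genotype"].isin(["G1", "G2"])], "2021-07-01", PARAMS)
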