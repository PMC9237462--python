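"""PCA summaries, repeated-measures ANOVA with sphericity handling,
post-hocs, clustering and phoneme-group aggregation."""

import numpy as np
import pandas as pd
import pytest

from sylentrain.group_stats import (
    FIVE_GROUP,
    THREE_GROUP,
    VOICING_STOPS,
    GroupDesign,
    bonferroni_posthoc,
    group_aggregate,
    itpc_components,
    kmeans_conditions,
    marker_components,
    pca,
    pearson,
    rm_anova_gg,
)


class TestPCA:
    def test_single_varying_variable(self, rng):
        X = np.zeros((20, 3))
        X[:, 1] = rng.standard_normal(20)
        cs = pca(X)
        assert cs.explained[0] == pytest.approx(1.0)

    def test_rotation_invariant_explained(self, rng):
        X = rng.standard_normal((50, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        a = pca(X).explained
        b = pca(X @ Q).explained
        assert np.allclose(a, b, atol=1e-10)

    def test_known_covariance_eigenfractions(self, rng):
        # build data whose sample covariance is exactly [[2,1],[1,2]]
        Z = rng.standard_normal((500, 2))
        Z -= Z.mean(0)
        # whiten exactly, then color with the target Cholesky factor
        cov = Z.T @ Z / (Z.shape[0] - 1)
        Z = Z @ np.linalg.inv(np.linalg.cholesky(cov)).T
        X = Z @ np.linalg.cholesky([[2.0, 1.0], [1.0, 2.0]]).T
        cs = pca(X)
        assert np.allclose(cs.explained, [0.75, 0.25], atol=1e-10)

    def test_reconstruction_from_all_components(self, rng):
        X = rng.standard_normal((30, 4))
        cs = pca(X)
        recon = cs.scores @ cs.loadings.T + X.mean(0)
        assert np.allclose(recon, X, atol=1e-10)

    def test_sign_convention(self, rng):
        cs = pca(rng.standard_normal((40, 3)))
        for j in range(cs.loadings.shape[1]):
            i = np.argmax(np.abs(cs.loadings[:, j]))
            assert cs.loadings[i, j] > 0


class TestItpcComponents:
    def freq_table(self, X):
        df = pd.DataFrame(X, columns=[4.0, 8.0, 12.0, 16.0])
        df["participant"] = [f"p{i}" for i in range(len(df))]
        return df

    def test_perfectly_correlated_frequencies(self, rng):
        base = rng.uniform(0.1, 0.4, 60)
        X = np.column_stack([base * w for w in (1.0, 0.8, 0.6, 0.4)])
        out, cs = itpc_components(self.freq_table(X))
        assert cs.explained[0] > 0.999
        assert np.allclose(out["ITPC2"], 0.0, atol=1e-8)

    def test_planted_two_factor_structure(self, rng):
        f1 = rng.standard_normal(4000)
        f2 = rng.standard_normal(4000)
        X = np.column_stack([
            1.0 * f1 + 0.1 * f2, 0.8 * f1 + 0.2 * f2,
            0.2 * f1 + 0.8 * f2, 0.1 * f1 + 1.0 * f2,
        ]) + 0.05 * rng.standard_normal((4000, 4))
        C = np.cov(X.T)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        planted = eig / eig.sum()
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, cs = itpc_components(self.freq_table(X))
        assert np.allclose(cs.explained[:2], planted[:2], atol=0.05)

    def test_missing_frequency_errors(self):
        df = pd.DataFrame(np.random.rand(5, 3), columns=[4.0, 8.0, 12.0])
        with pytest.raises(ValueError, match="missing"):
            itpc_components(df)


class TestMarkerComponents:
    def marker_table(self, rng, n=15):
        cols = ("md_latency", "ma_latency", "sharpness", "gini", "plateau")
        return pd.DataFrame(rng.uniform(1, 2, (n, 5)), columns=cols)

    def test_unit_change_invariance(self, rng):
        df = self.marker_table(rng)
        out1, _ = marker_components(df)
        df2 = df.copy()
        df2["md_latency"] *= 1000.0  # ms -> arbitrary rescale
        out2, _ = marker_components(df2)
        assert np.allclose(out1["PC1"], out2["PC1"], atol=1e-8)

    def test_perfectly_correlated_markers(self, rng):
        base = rng.standard_normal(15)
        df = pd.DataFrame({k: base * (i + 1) for i, k in enumerate(
            ("md_latency", "ma_latency", "sharpness", "gini", "plateau"))})
        _, cs = marker_components(df)
        assert cs.explained[0] > 0.999

    def test_zero_variance_marker_named(self, rng):
        df = self.marker_table(rng)
        df["gini"] = 0.3
        with pytest.raises(ValueError, match="gini"):
            marker_components(df)


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = pearson(x, x)
        assert r == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.arange(10.0)
        r, _ = pearson(x, -2 * x + 3)
        assert r == pytest.approx(-1.0)

    def test_p_transform_at_paper_n(self, rng):
        """n=25 pairs with sample r = 0.54 must give two-sided p ~ 0.005-0.006."""
        x = rng.standard_normal(25)
        resid = rng.standard_normal(25)
        # orthogonalize and normalize so the empirical correlation is exact
        x = (x - x.mean()) / x.std()
        resid -= resid.mean()
        resid -= x * (resid @ x) / (x @ x)
        resid /= resid.std()
        target = 0.54
        y = target * x + np.sqrt(1 - target**2) * resid
        r, p = pearson(x, y)
        assert r == pytest.approx(0.54, abs=1e-12)
        assert 0.005 <= p <= 0.006

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson(np.ones(5), np.arange(5.0))


class TestRmAnova:
    def test_two_conditions_epsilon_one(self, rng):
        rep = rm_anova_gg(rng.standard_normal((10, 2)))
        assert rep.epsilon == 1.0

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        data = rng.standard_normal((8, 4)) + np.array([0, 0.3, 0.1, 0.6])
        rep = rm_anova_gg(data)
        df = pd.DataFrame(data).reset_index().melt(
            id_vars="index", var_name="cond", value_name="y")
        aov = pg.rm_anova(data=df, dv="y", within="cond", subject="index",
                          correction=True)
        assert rep.F == pytest.approx(float(aov["F"].iloc[0]), rel=1e-8)
        assert rep.p_uncorrected == pytest.approx(float(aov["p_unc"].iloc[0]), rel=1e-8)
        assert rep.epsilon == pytest.approx(float(aov["eps"].iloc[0]), rel=1e-8)
        assert rep.p_gg == pytest.approx(float(aov["p_GG_corr"].iloc[0]), rel=1e-6)
        sph = pg.sphericity(data=df, dv="y", within="cond", subject="index")
        assert rep.mauchly_W == pytest.approx(float(sph.W), rel=1e-8)
        assert rep.mauchly_p == pytest.approx(float(sph.pval), abs=0.02)

    def test_planted_effect_detected(self, rng):
        data = rng.standard_normal((12, 4)) * 0.01 + np.array([0, 1, 2, 3])
        rep = rm_anova_gg(data)
        assert rep.p < 0.001

    def test_gg_with_unit_epsilon_equals_uncorrected(self, rng):
        rep = rm_anova_gg(rng.standard_normal((10, 2)))
        assert rep.p_gg == pytest.approx(rep.p_uncorrected)

    def test_shape_validation(self, rng):
        with pytest.raises(ValueError):
            rm_anova_gg(rng.standard_normal((1, 4)))


class TestBonferroni:
    def test_identical_samples(self, rng):
        x = rng.standard_normal(10)
        df = pd.DataFrame({"a": x, "b": x})
        out = bonferroni_posthoc(df)
        assert out.loc[0, "t"] == 0.0
        assert out.loc[0, "p_bonferroni"] == 1.0

    def test_single_comparison_no_inflation(self, rng):
        df = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        out = bonferroni_posthoc(df, pairs=[("a", "b")])
        assert out.loc[0, "p_bonferroni"] == pytest.approx(out.loc[0, "p_raw"])

    def test_multiplication_rule(self, rng):
        df = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        out = bonferroni_posthoc(df)
        assert len(out) == 3
        for _, row in out.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, 3 * row["p_raw"]))


class TestKmeans:
    def test_three_separated_blobs_recovered(self, rng):
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        X = np.vstack([c + 0.1 * rng.standard_normal((5, 2)) for c in centers])
        labels = kmeans_conditions(X, k=3, restarts=20, seed=0)
        for i in range(3):
            assert len(set(labels[i * 5 : (i + 1) * 5])) == 1
        assert len(set(labels)) == 3

    def test_k_one_single_cluster(self, rng):
        labels = kmeans_conditions(rng.standard_normal((8, 2)), k=1, restarts=5)
        assert set(labels) == {0}

    def test_duplicates_share_cluster(self, rng):
        X = np.vstack([rng.standard_normal((6, 2))] * 2)
        labels = kmeans_conditions(X, k=3, restarts=20, seed=1)
        assert np.array_equal(labels[:6], labels[6:])

    def test_k_exceeds_conditions(self, rng):
        with pytest.raises(ValueError):
            kmeans_conditions(rng.standard_normal((2, 2)), k=3)


class TestGroupAggregate:
    def scores_frame(self, conditions, rng, n_part=4):
        rows = []
        for p in range(n_part):
            for c in conditions:
                rows.append({"participant": f"p{p}", "condition": c,
                             "ITPC1": rng.uniform(0, 1)})
        return pd.DataFrame(rows)

    def test_three_group_partition_contents(self):
        assert set(THREE_GROUP["stops"]) == {"b", "d", "g", "k", "p", "t"}
        assert set(THREE_GROUP["fricatives_sibilants"]) == {"f", "v", "s", "z"}
        assert set(THREE_GROUP["nasals_liquids"]) == {"m", "n", "l", "r"}

    def test_voicing_partition_of_stops(self):
        assert set(VOICING_STOPS["voiced"]) == {"b", "d", "g"}
        assert set(VOICING_STOPS["unvoiced"]) == {"k", "p", "t"}

    def test_five_group_covers_all_consonants(self):
        members = {c for g in FIVE_GROUP.values() for c in g}
        assert members == {c for g in THREE_GROUP.values() for c in g}

    def test_singleton_groups_equal_condition_means(self, rng):
        design = GroupDesign(partitions={"solo": {"gb": ("b",), "gs": ("s",)}})
        df = self.scores_frame(["b", "s"], rng)
        tidy = group_aggregate(df, design, "solo")
        for grp, cond in (("gb", "b"), ("gs", "s")):
            got = tidy[tidy.group == grp].sort_values("participant")["ITPC1"].to_numpy()
            want = df[df.condition == cond].sort_values("participant")["ITPC1"].to_numpy()
            assert np.allclose(got, want)

    def test_vowel_condition_dropped(self, rng):
        design = GroupDesign()
        df = self.scores_frame(["b", "f", "m", "V"], rng)
        tidy = group_aggregate(df, design, "three_group")
        assert "V" not in set(tidy["group"])
        assert len(tidy["group"].unique()) == 3

    def test_unknown_condition_errors(self, rng):
        design = GroupDesign()
        df = self.scores_frame(["b", "x"], rng)
        with pytest.raises(ValueError, match="unknown"):
            group_aggregate(df, design, "three_group")
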