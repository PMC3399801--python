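"""Canonical and stepwise discriminant analysis, classification, pairwise F."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trabkit.allometry import LOCOMOTOR_GROUPS
from trabkit.discriminant import (CanonicalDiscriminant, ConfusionMatrix,
                                  stepwise_select)
from trabkit.phantoms import locomotor_demo_centroids, simulate_groups

# printed classification-table counts for the femoral-head analysis
FEMUR_COUNTS = [[17, 0, 2, 1, 0, 0, 0],
                [0, 8, 1, 1, 1, 0, 0],
                [4, 8, 22, 1, 5, 0, 0],
                [0, 0, 0, 12, 0, 1, 0],
                [1, 0, 1, 1, 4, 0, 0],
                [0, 0, 1, 0, 1, 5, 0],
                [0, 0, 0, 0, 0, 0, 17]]


def _two_group_1d():
    x = pd.DataFrame({"v": [-0.2, 0.0, 0.2, 0.8, 1.0, 1.2]})
    g = pd.Series(["a", "a", "a", "b", "b", "b"])
    return x, g


class TestConfusionMatrix:
    def test_overall_and_per_group_percentages(self):
        cm = ConfusionMatrix.from_counts(FEMUR_COUNTS, LOCOMOTOR_GROUPS)
        assert cm.overall_percent == 73.9
        assert cm.n_correct == 85
        assert cm.percent_correct.tolist() == [85.0, 72.7, 55.0, 92.3,
                                               57.1, 71.4, 100.0]

    def test_perfect_predictions(self):
        cm = ConfusionMatrix.from_counts(np.diag([3, 4, 5]), ["x", "y", "z"])
        assert cm.overall_percent == 100.0
        assert (cm.percent_correct == 100.0).all()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            ConfusionMatrix.from_labels(["x", "q"], ["x", "x"], ["x", "y"])


class TestFit:
    def test_one_dimensional_two_groups(self):
        x, g = _two_group_1d()
        res = CanonicalDiscriminant(x, g).fit()
        assert len(res.eigenvalues) == 1
        # equal priors → decision boundary at the midpoint of the means
        pred = res.predict(pd.DataFrame({"v": [0.49, 0.51]}))
        assert pred.tolist() == ["a", "b"]

    def test_identical_group_means_give_unit_wilks(self):
        x = pd.DataFrame({"v1": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                          "v2": [0.0, 2.0, 1.0, 0.0, 2.0, 1.0]})
        g = pd.Series(["a"] * 3 + ["b"] * 3)
        res = CanonicalDiscriminant(x, g).fit()
        assert res.wilks[0] == pytest.approx(1.0, abs=1e-10)
        assert res.eigenvalues[0] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("p,expected_m", [(5, 5), (3, 3)])
    def test_number_of_functions(self, p, expected_m):
        cent = locomotor_demo_centroids(2.0).iloc[:, :p]
        tab = simulate_groups(cent, np.eye(p), 10, seed=0)
        res = CanonicalDiscriminant(tab[cent.columns], tab["group"]).fit()
        assert res.coef.shape == (p, expected_m)  # m = min(g−1, p)

    def test_percent_variance_sums_to_hundred(self):
        cent = locomotor_demo_centroids(2.0)
        tab = simulate_groups(cent, np.eye(5), 12, seed=3)
        res = CanonicalDiscriminant(tab[cent.columns], tab["group"]).fit()
        assert res.pct_variance.sum() == pytest.approx(100.0)

    def test_affine_invariance_of_wilks_and_classification(self):
        cent = locomotor_demo_centroids(2.0)
        tab = simulate_groups(cent, np.eye(5), 12, seed=5)
        X = tab[cent.columns]
        res1 = CanonicalDiscriminant(X, tab["group"]).fit()
        A = np.array([[2.0, 0.3, 0, 0, 0],
                      [0, 1.5, 0, 0, 0.2],
                      [0.1, 0, 0.8, 0, 0],
                      [0, 0, 0, 3.0, 0],
                      [0, 0, 0.4, 0, 1.1]])
        X2 = pd.DataFrame(X.to_numpy() @ A + 7.0, columns=X.columns)
        res2 = CanonicalDiscriminant(X2, tab["group"]).fit()
        assert res2.wilks[0] == pytest.approx(res1.wilks[0], rel=1e-8)
        assert res2.predict().tolist() == res1.predict().tolist()

    def test_structure_matrix_is_within_group_correlation(self):
        cent = locomotor_demo_centroids(2.0)
        tab = simulate_groups(cent, np.eye(5), 30, seed=8)
        res = CanonicalDiscriminant(tab[cent.columns], tab["group"]).fit()
        # oracle: correlate group-mean-centred variables with scores
        Xc = tab[cent.columns].copy()
        scores = res.scores().to_numpy()
        for g, sub in tab.groupby("group").groups.items():
            Xc.loc[sub] -= tab.loc[sub, cent.columns].mean()
        s_centred = scores.copy()
        for g, sub in tab.groupby("group").groups.items():
            s_centred[np.asarray(sub)] -= scores[np.asarray(sub)].mean(axis=0)
        r_oracle = np.corrcoef(Xc.to_numpy().T, s_centred.T)[:5, 5:]
        assert np.allclose(res.structure_matrix.to_numpy(), r_oracle,
                           atol=0.02)


class TestClassification:
    def test_observation_at_centroid_goes_to_its_group(self):
        cent = locomotor_demo_centroids(2.5)
        tab = simulate_groups(cent, np.eye(5), 20, seed=2)
        res = CanonicalDiscriminant(tab[cent.columns], tab["group"]).fit()
        pred = res.predict(res.group_means)
        assert pred.tolist() == list(res.group_means.index)

    def test_agreement_with_brute_force_mahalanobis_oracle(self):
        cent = locomotor_demo_centroids(1.5).iloc[:5]
        tab = simulate_groups(cent, np.eye(5) + 0.3, 20, seed=6)
        res = CanonicalDiscriminant(tab[cent.columns], tab["group"]).fit()
        Sw_inv = np.linalg.inv(res.pooled_within_cov.to_numpy())
        oracle = []
        for _, row in tab[cent.columns].iterrows():
            d2 = {g: (row.to_numpy() - res.group_means.loc[g].to_numpy())
                  @ Sw_inv @ (row.to_numpy()
                              - res.group_means.loc[g].to_numpy())
                  for g in res.group_means.index}
            oracle.append(min(d2, key=d2.get))
        assert res.predict().tolist() == oracle

    def test_agreement_with_reference_lda_implementation(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        cent = locomotor_demo_centroids(2.0)
        tab = simulate_groups(cent, np.eye(5) + 0.1, 15, seed=13)
        res = CanonicalDiscriminant(tab[cent.columns], tab["group"]).fit()
        ref = LinearDiscriminantAnalysis(priors=[1 / 7] * 7)
        ref.fit(tab[cent.columns], tab["group"])
        assert (ref.predict(tab[cent.columns])
                == res.predict().to_numpy()).all()

    def test_score_plot_renders(self):
        import matplotlib

        matplotlib.use("Agg")
        cent = locomotor_demo_centroids(2.0)
        tab = simulate_groups(cent, np.eye(5), 10, seed=4)
        res = CanonicalDiscriminant(tab[cent.columns], tab["group"]).fit()
        ax = res.plot_scores()
        assert len(ax.collections) == 7

    def test_loo_not_better_than_resubstitution_on_average(self):
        accs = []
        for seed in range(3):
            cent = locomotor_demo_centroids(1.2).iloc[:4]
            tab = simulate_groups(cent, np.eye(5), 12, seed=seed)
            res = CanonicalDiscriminant(tab[cent.columns], tab["group"]).fit()
            resub = res.confusion().overall_percent
            loo = ConfusionMatrix.from_labels(
                res.predict_loo(), tab["group"],
                res.model.group_order).overall_percent
            accs.append(resub - loo)
        assert np.mean(accs) >= 0.0

    def test_dimension_mismatch_rejected(self):
        x, g = _two_group_1d()
        res = CanonicalDiscriminant(x, g).fit()
        with pytest.raises(ValueError, match="lack"):
            res.predict(pd.DataFrame({"other": [1.0]}))


class TestStepwise:
    def test_single_informative_variable_selected(self):
        rng = np.random.default_rng(42)
        groups = pd.Series(np.repeat(["a", "b", "c"], 50))
        X = pd.DataFrame(rng.standard_normal((150, 5)),
                         columns=list("vwxyz"))
        X["v"] += np.repeat([0.0, 2.0, 4.0], 50)  # effect size 2 SD per step
        assert stepwise_select(X, groups) == ["v"]

    def test_all_noise_selects_nothing(self):
        rng = np.random.default_rng(3)
        groups = pd.Series(np.repeat(["a", "b", "c"], 50))
        X = pd.DataFrame(rng.standard_normal((150, 5)),
                         columns=list("vwxyz"))
        assert stepwise_select(X, groups) == []

    def test_selection_deterministic(self):
        cent = locomotor_demo_centroids(2.5)
        tab = simulate_groups(cent, np.eye(5), 15, seed=9)
        a = stepwise_select(tab[cent.columns], tab["group"])
        b = stepwise_select(tab[cent.columns], tab["group"])
        assert a == b and len(a) >= 1

    def test_inverted_thresholds_rejected(self):
        x, g = _two_group_1d()
        with pytest.raises(ValueError):
            stepwise_select(x, g, f_enter=1.0, f_remove=2.0)


class TestPairwiseF:
    def test_degrees_of_freedom_for_study_design(self):
        # n = 115, g = 7, p = 3 → DF = (3, 106)
        rng = np.random.default_rng(0)
        sizes = [20, 11, 40, 13, 7, 7, 17]
        groups = pd.Series(np.repeat(LOCOMOTOR_GROUPS, sizes))
        X = pd.DataFrame(rng.standard_normal((115, 3)),
                         columns=["da", "tb_n", "conn_d"])
        res = CanonicalDiscriminant(X, groups).fit()
        assert res.pairwise_f().df == (3, 106)

    def test_identical_centroids_give_zero_f(self):
        x = pd.DataFrame({"v1": [1.0, 2.0, 3.0] * 4,
                          "v2": [2.0, 0.0, 1.0] * 4})
        g = pd.Series(["a"] * 3 + ["b"] * 3 + ["a"] * 3 + ["b"] * 3)
        res = CanonicalDiscriminant(x, g).fit()
        pw = res.pairwise_f()
        assert pw.f.loc["a", "b"] == pytest.approx(0.0, abs=1e-10)
        assert pw.p.loc["a", "b"] == pytest.approx(1.0)

    def test_two_group_hotelling_identity(self):
        # F from D² must equal Hotelling's T² · (n−p−1)/(p(n−2))
        rng = np.random.default_rng(5)
        n1, n2, p = 14, 11, 3
        X = pd.DataFrame(rng.standard_normal((n1 + n2, p)),
                         columns=list("abc"))
        X.iloc[:n1] += 1.0
        g = pd.Series(["g1"] * n1 + ["g2"] * n2)
        res = CanonicalDiscriminant(X, g).fit()
        pw = res.pairwise_f()
        Sw_inv = np.linalg.inv(res.pooled_within_cov.to_numpy())
        d = (res.group_means.loc["g1"] - res.group_means.loc["g2"]).to_numpy()
        t2 = (n1 * n2) / (n1 + n2) * d @ Sw_inv @ d
        f_oracle = t2 * (n1 + n2 - p - 1) / (p * (n1 + n2 - 2))
        assert pw.f.loc["g1", "g2"] == pytest.approx(f_oracle, rel=1e-10)
        df1, df2 = pw.df
        assert pw.p.loc["g1", "g2"] == pytest.approx(
            stats.f.sf(f_oracle, df1, df2), rel=1e-10)

    def test_too_many_variables_rejected(self):
        x = pd.DataFrame(np.random.default_rng(1).standard_normal((6, 4)),
                         columns=list("abcd"))
        g = pd.Series(["x"] * 3 + ["y"] * 3)
        res = CanonicalDiscriminant(x, g).fit()
        with pytest.raises(ValueError):
            res.pairwise_f()


class TestGroupRecovery:
    def test_separated_centroids_recovered(self):
        cent = locomotor_demo_centroids(2.5)
        tab = simulate_groups(cent, np.eye(5), 15, seed=20)
        model = CanonicalDiscriminant(tab[cent.columns], tab["group"])
        res = model.fit_stepwise()
        assert res.confusion().overall_percent >= 90.0

    def test_coincident_centroids_at_chance(self):
        cent = locomotor_demo_centroids(0.0)
        accs = []
        for seed in range(30):
            tab = simulate_groups(cent, np.eye(5), 15, seed=seed)
            res = CanonicalDiscriminant(tab[cent.columns],
                                        tab["group"]).fit()
            accs.append(res.confusion().overall_percent)
        # chance level 1/7 ≈ 14.3% plus resubstitution optimism
        assert abs(np.mean(accs) - 100.0 / 7) < 15.0
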