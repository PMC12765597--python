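"""Feature screening, discriminant analysis, holdout assignment and the
Mahalanobis acoustic distance matrix."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import batdialect as bd


def gaussian_colonies(means, n_per=30, sd=1.0, seed=0, columns=None):
    """Feature table with one Gaussian cluster per colony."""
    rng = np.random.default_rng(seed)
    means = np.atleast_2d(np.asarray(means, dtype=float))
    k, p = means.shape
    columns = columns or [f"x{j}" for j in range(p)]
    rows = []
    for c in range(k):
        sample = means[c] + sd * rng.standard_normal((n_per, p))
        for row in sample:
            rows.append({"colony": f"c{c}", **dict(zip(columns, row))})
    return pd.DataFrame(rows)


class TestScreenFeatures:
    def test_hand_computed_f_statistic(self):
        df = pd.DataFrame({"colony": list("aaabbb"),
                           "x": [1.0, 2, 3, 2, 3, 4]})
        rep = bd.screen_features(df, feature_cols=["x"])
        row = rep.anova.iloc[0]
        assert row["F"] == pytest.approx(1.5)
        assert (row["df1"], row["df2"]) == (1.0, 4.0)

    def test_null_retention_rate_close_to_alpha(self):
        """Five colonies drawn from one normal: the screen should retain
        the feature in ~alpha of repetitions (500 reps, +-2 binomial sd;
        derandomised Monte Carlo)."""
        rng = np.random.default_rng(1)
        n_rep, alpha = 500, 0.05
        hits = 0
        for _ in range(n_rep):
            df = pd.DataFrame({
                "colony": np.repeat([f"c{i}" for i in range(5)], 12),
                "x": rng.standard_normal(60),
            })
            hits += bool(bd.screen_features(df, alpha=alpha,
                                            feature_cols=["x"]).informative)
        rate = hits / n_rep
        sd = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) <= 2 * sd

    def test_shifted_colony_flagged_by_tukey(self):
        df = gaussian_colonies([[0.0], [0.0], [5.0], [0.0], [0.0]],
                               n_per=20, sd=1.0, seed=1, columns=["x"])
        rep = bd.screen_features(df, feature_cols=["x"])
        assert rep.informative == ["x"]
        tuk = rep.tukey["x"]
        sig = tuk[tuk["reject"] == True]  # noqa: E712
        involved = set(sig["group1"]).union(sig["group2"])
        flagged_pairs = {frozenset(p) for p in
                         zip(sig["group1"], sig["group2"])}
        expected = {frozenset(("c2", other))
                    for other in ("c0", "c1", "c3", "c4")}
        assert flagged_pairs == expected
        assert "c2" in involved

    def test_constant_feature_excluded_with_warning_entry(self):
        df = gaussian_colonies([[0.0], [3.0]], n_per=10, seed=2, columns=["x"])
        df["const"] = 1.0
        rep = bd.screen_features(df, feature_cols=["x", "const"])
        assert rep.excluded_constant == ["const"]
        assert rep.informative == ["x"]


class TestFitDiscriminant:
    def test_two_class_axis_matches_closed_form_direction(self):
        """With identity within-class covariance the first discriminant is
        parallel to the mean difference."""
        df = gaussian_colonies([[0.0, 0.0], [4.0, 0.0]], n_per=300, sd=1.0,
                               seed=3)
        model, _ = bd.fit_discriminant(df, df["colony"], ["x0", "x1"])
        ld1 = model.discriminant_axes[:, 0]
        cos = abs(ld1[0]) / np.linalg.norm(ld1)
        assert cos > 0.99

    def test_axis_count_is_rank_bounded(self):
        df = gaussian_colonies(np.random.default_rng(4).normal(size=(5, 2)),
                               n_per=20, sd=0.5, seed=4)
        model, scores = bd.fit_discriminant(df, df["colony"], ["x0", "x1"])
        assert model.n_axes == 2  # min(k-1, p) = min(4, 2)
        assert list(scores.columns[:2]) == ["LD1", "LD2"]
        assert np.all(np.diff(model.axis_eigenvalues) <= 1e-9)

    def test_duplicating_observations_leaves_axis_directions_unchanged(self):
        df = gaussian_colonies([[0, 0], [3, 1], [1, 4]], n_per=25, seed=5)
        m1, _ = bd.fit_discriminant(df, df["colony"], ["x0", "x1"])
        doubled = pd.concat([df, df], ignore_index=True)
        m2, _ = bd.fit_discriminant(doubled, doubled["colony"], ["x0", "x1"])
        for j in range(m1.n_axes):
            a, b = m1.discriminant_axes[:, j], m2.discriminant_axes[:, j]
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos == pytest.approx(1.0, abs=1e-9)

    def test_axes_orthonormal_in_within_class_metric(self):
        df = gaussian_colonies([[0, 0, 1], [2, 1, 0], [1, 3, 2]],
                               n_per=40, seed=6)
        model, _ = bd.fit_discriminant(df, df["colony"], ["x0", "x1", "x2"])
        gram = model.discriminant_axes.T @ model.pooled_within_cov \
            @ model.discriminant_axes
        assert np.allclose(gram, np.eye(model.n_axes), atol=1e-8)

    def test_scores_match_sklearn_lda_up_to_axis_sign(self):
        df = gaussian_colonies([[0, 0], [3, 1], [1, 4]], n_per=30, seed=7)
        model, scores = bd.fit_discriminant(df, df["colony"], ["x0", "x1"])
        ref = LinearDiscriminantAnalysis(solver="eigen")
        ref_scores = ref.fit_transform(df[["x0", "x1"]], df["colony"])
        for j in range(2):
            ours = scores[f"LD{j + 1}"].to_numpy()
            theirs = ref_scores[:, j]
            corr = abs(np.corrcoef(ours, theirs)[0, 1])
            assert corr > 0.9999

    def test_predictions_match_sklearn_lda(self):
        df = gaussian_colonies([[0, 0], [2.5, 1], [1, 3]], n_per=30, seed=8)
        model, _ = bd.fit_discriminant(df, df["colony"], ["x0", "x1"])
        x = df[["x0", "x1"]].to_numpy()
        ref = LinearDiscriminantAnalysis(solver="lsqr")
        ref.fit(x, df["colony"])
        agree = (model.predict(x) == ref.predict(x)).mean()
        assert agree > 0.99

    def test_ld1_screen_is_emitted(self):
        df = gaussian_colonies([[0, 0], [4, 0]], n_per=25, seed=9)
        model, _ = bd.fit_discriminant(df, df["colony"], ["x0", "x1"])
        assert model.ld1_screen is not None
        assert model.ld1_screen.informative == ["LD1"]


class TestClassifyHoldout:
    def test_well_separated_colonies_classified_above_95_pct(self):
        df = gaussian_colonies(
            [[0, 0], [6, 0], [0, 6], [6, 6]], n_per=40, sd=1.0, seed=10)
        rep = bd.classify_holdout(df, df["colony"], ["x0", "x1"], seed=0)
        assert rep.overall_pct_correct >= 95.0
        assert rep.confusion.to_numpy().sum() == 80  # half of 160 held out

    def test_permuted_labels_fall_to_chance_level(self):
        rng = np.random.default_rng(11)
        df = gaussian_colonies(np.zeros((5, 3)), n_per=40, sd=1.0, seed=11)
        df["colony"] = rng.permutation(df["colony"].to_numpy())
        accs = [bd.classify_holdout(df, df["colony"], ["x0", "x1", "x2"],
                                    seed=s).overall_pct_correct
                for s in range(10)]
        mean_acc = np.mean(accs) / 100.0
        # binomial error around 1/k = 0.2 with 100 test calls x 10 reps
        assert abs(mean_acc - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 1000)

    def test_single_colony_is_trivially_perfect(self):
        df = gaussian_colonies([[0.0, 0.0]], n_per=10, seed=12)
        rep = bd.classify_holdout(df, df["colony"], ["x0", "x1"], seed=0)
        assert rep.overall_pct_correct == 100.0

    def test_colony_with_single_exemplar_errors_by_name(self):
        df = gaussian_colonies([[0, 0], [4, 4]], n_per=5, seed=13)
        df = df.drop(df[df.colony == "c1"].index[1:])
        with pytest.raises(ValueError, match="c1"):
            bd.classify_holdout(df, df["colony"], ["x0", "x1"], seed=0)

    def test_confusion_rows_sum_to_test_counts(self):
        df = gaussian_colonies([[0, 0], [3, 0], [0, 3]], n_per=21, seed=14)
        rep = bd.classify_holdout(df, df["colony"], ["x0", "x1"], seed=1)
        for c in rep.confusion.index:
            n_test = rep.confusion.loc[c].sum()
            assert n_test in (10, 11)


class TestAcousticDistance:
    def scores_frame(self, means, n_per=40, sd=1.0, seed=0):
        df = gaussian_colonies(means, n_per=n_per, sd=sd, seed=seed,
                               columns=["LD1", "LD2"])
        return df

    def test_identity_covariance_reduces_to_squared_euclidean(self):
        rng = np.random.default_rng(15)
        means = rng.normal(size=(4, 2)) * 5
        df = self.scores_frame(means, n_per=4000, sd=1.0, seed=15)
        d = bd.acoustic_distance_matrix(df)
        emp_means = df.groupby("colony")[["LD1", "LD2"]].mean()
        for i, ci in enumerate(d.labels):
            for j, cj in enumerate(d.labels):
                expected = np.sum(
                    (emp_means.loc[ci] - emp_means.loc[cj]) ** 2)
                # pooled covariance ~ identity at n = 4000 per colony
                assert d.values[i, j] == pytest.approx(expected, rel=0.05,
                                                       abs=1e-9)

    def test_identical_distributions_give_near_zero_distance(self):
        df = self.scores_frame([[1.0, 1.0], [1.0, 1.0]], n_per=2000, seed=16)
        d = bd.acoustic_distance_matrix(df)
        assert d.values[0, 1] == pytest.approx(0.0, abs=0.01)

    def test_affine_invariance_under_axis_rescaling(self):
        df = self.scores_frame([[0, 0], [3, 1], [1, 2]], n_per=50, seed=17)
        d1 = bd.acoustic_distance_matrix(df)
        scaled = df.copy()
        scaled["LD2"] = scaled["LD2"] * 10.0
        d2 = bd.acoustic_distance_matrix(scaled)
        assert np.allclose(d1.values, d2.values, atol=1e-8)

    def test_exemplar_to_centroid_table_shape(self):
        df = self.scores_frame([[0, 0], [3, 1]], n_per=10, seed=18)
        tab = bd.exemplar_centroid_distances(df)
        assert len(tab) == 20
        assert {"d2_to_c0", "d2_to_c1", "colony"} <= set(tab.columns)
        assert (tab[["d2_to_c0", "d2_to_c1"]].to_numpy() >= 0).all()

    def test_mean_exemplar_variant_is_symmetric(self):
        df = self.scores_frame([[0, 0], [3, 1], [1, 2]], n_per=30, seed=19)
        d = bd.acoustic_distance_matrix(df, pair_stat="mean_exemplar")
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0.0)
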