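import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from ascakit.exceptions import ConfigurationError, DesignError
from ascakit.io import autoscale, normalize
from ascakit.reference import (
    SR_CAP,
    bh_adjust,
    fit_pca,
    fit_plsda,
    selectivity_ratio,
    stability_replicates,
    univariate_tests,
    vip_scores,
)

from conftest import make_design


class TestFitPca:
    def test_rank_one_single_component(self):
        X = np.outer([1.0, 2.0, 3.0, 4.0], [1.0, -1.0, 2.0])
        model = fit_pca(X, scaling="center")
        assert model.explained[0] == pytest.approx(1.0)

    def test_reconstruction_oracle(self, rng):
        X = rng.normal(size=(8, 5))
        model = fit_pca(X, scaling="center")
        np.testing.assert_allclose(
            model.scores @ model.loadings.T, X - X.mean(axis=0), atol=1e-9
        )

    def test_explained_fractions_shape(self, rng):
        X = rng.normal(size=(6, 10))
        model = fit_pca(X, scaling="autoscale")
        assert np.all(np.diff(model.explained) <= 1e-12)  # non-increasing
        assert model.explained.sum() <= 1.0 + 1e-9


class TestFitPlsda:
    def test_deterministic(self, rng):
        X = rng.normal(size=(10, 8))
        classes = ["A"] * 5 + ["B"] * 5
        m1 = fit_plsda(X, classes, n_latent=2)
        m2 = fit_plsda(X, classes, n_latent=2)
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_perfectly_separated_single_variable(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        model = fit_plsda(X, ["A"] * 3 + ["B"] * 3, n_latent=1)
        assert model.explained_y[0] > 0.95

    def test_training_predictions_correct_when_separated(self, marker_dataset):
        ds = marker_dataset
        X = autoscale(
            normalize(ds.features, ds.design).drop_internal_standards().values
        )
        classes = ds.design.factors["group"]
        model = fit_plsda(X, classes, n_latent=2)
        assert model.predict_classes(X) == classes

    def test_three_class_encoding(self, rng):
        X = rng.normal(size=(9, 6))
        classes = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        model = fit_plsda(X, classes, n_latent=2)
        assert model.y_loadings.shape[0] == 3
        assert model.classes == ["a", "b", "c"]

    def test_two_class_single_indicator(self, rng):
        X = rng.normal(size=(8, 6))
        model = fit_plsda(X, ["A"] * 4 + ["B"] * 4, n_latent=2)
        assert model.y_loadings.shape[0] == 1

    def test_single_class_error(self, rng):
        with pytest.raises(DesignError):
            fit_plsda(rng.normal(size=(4, 3)), ["A"] * 4)

    def test_weight_columns_unit_norm(self, rng):
        X = rng.normal(size=(12, 20))
        model = fit_plsda(X, ["A"] * 6 + ["B"] * 6, n_latent=3)
        np.testing.assert_allclose(
            np.linalg.norm(model.weights, axis=0), 1.0, atol=1e-12
        )


class TestVip:
    @pytest.mark.parametrize("n_latent", [1, 2, 3])
    def test_mean_squared_vip_is_one(self, rng, n_latent):
        X = rng.normal(size=(14, 25))
        X[7:, :5] += 1.0
        model = fit_plsda(X, ["A"] * 7 + ["B"] * 7, n_latent=n_latent)
        v = vip_scores(model)
        assert np.mean(v**2) == pytest.approx(1.0, abs=1e-12)
        assert np.sum(v**2) == pytest.approx(25.0, abs=1e-10)

    def test_single_variable_vip_is_one(self):
        X = np.array([[0.0], [1.0], [3.0], [4.0]])
        model = fit_plsda(X, ["A", "A", "B", "B"], n_latent=1)
        assert vip_scores(model)[0] == pytest.approx(1.0)

    def test_zero_weight_variable_vip_zero(self, rng):
        X = rng.normal(size=(8, 4))
        X[:, 3] = 2.5  # constant -> centered to zero -> zero weight
        model = fit_plsda(X, ["A"] * 4 + ["B"] * 4, n_latent=2)
        assert vip_scores(model)[3] == pytest.approx(0.0, abs=1e-12)


class TestSelectivityRatio:
    def test_orthogonal_column_zero(self):
        # column 1 carries the class difference; column 2 is orthogonal to
        # the resulting target-projection scores by construction
        t = np.array([-1.0, -1.0, 1.0, 1.0])
        orth = np.array([1.0, -1.0, 1.0, -1.0])
        X = np.column_stack([t, orth])
        model = fit_plsda(X, ["A", "A", "B", "B"], n_latent=1)
        sr = selectivity_ratio(model, X)
        assert sr[1] == pytest.approx(0.0, abs=1e-18)
        assert sr[0] >= SR_CAP  # exactly explained -> capped

    def test_rank_one_data_hits_cap(self):
        direction = np.array([1.0, 2.0, -1.0])
        X = np.outer([0.0, 0.0, 1.0, 1.0], direction)
        model = fit_plsda(X, ["A", "A", "B", "B"], n_latent=1)
        sr = selectivity_ratio(model, X)
        assert np.all(sr == SR_CAP)

    def test_brute_force_oracle_random_data(self, rng):
        # direct-reconstruction oracle on a 6 x 20 dataset
        X = rng.normal(size=(6, 20))
        X[3:, :4] += 1.0
        model = fit_plsda(X, ["A"] * 3 + ["B"] * 3, n_latent=2)
        sr = selectivity_ratio(model, X)
        Xc = X - X.mean(axis=0)
        b = model.regression_vector()
        b = b / np.linalg.norm(b)
        t = Xc @ b
        p_tp = Xc.T @ t / (t @ t)
        expected = []
        for j in range(20):
            hat = t * p_tp[j]
            res = Xc[:, j] - hat
            expected.append(np.sum(hat**2) / np.sum(res**2))
        np.testing.assert_allclose(sr, expected, rtol=1e-9)


class TestStabilityReplicates:
    def test_fixed_seed_identical(self, rng):
        X = rng.normal(size=(10, 30))
        X[5:, :5] += 2.0
        classes = ["A"] * 5 + ["B"] * 5
        f1 = stability_replicates(X, classes, n_models=20, k=5, seed=3)
        f2 = stability_replicates(X, classes, n_models=20, k=5, seed=3)
        np.testing.assert_array_equal(f1, f2)

    def test_frequencies_in_unit_interval(self, rng):
        X = rng.normal(size=(10, 30))
        classes = ["A"] * 5 + ["B"] * 5
        f = stability_replicates(X, classes, n_models=15, k=5, seed=0)
        assert np.all((0 <= f) & (f <= 1))

    def test_strong_markers_always_selected(self, marker_dataset):
        ds = marker_dataset
        X = autoscale(
            normalize(ds.features, ds.design).drop_internal_standards().values
        )
        ids = ds.features.drop_internal_standards().variable_ids
        marker_idx = [ids.index(m) for m in ds.truth_markers]
        freq = stability_replicates(
            X, ds.design.factors["group"], n_models=50, k=20, seed=1
        )
        assert np.median(freq[marker_idx]) > 0.85

    def test_invalid_removal_range(self, rng):
        with pytest.raises(ConfigurationError):
            stability_replicates(
                rng.normal(size=(6, 10)), ["A"] * 3 + ["B"] * 3,
                removal_range=(0.5, 0.2),
            )


class TestUnivariate:
    def test_identical_groups_p_one(self):
        d = make_design(["A", "A", "B", "B"])
        X = np.array([[1.0], [1.0], [1.0], [1.0]])
        with pytest.warns(UserWarning, match="constant"):
            p = univariate_tests(X, d, "group")
        assert p[0] == 1.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_t_squared_equals_f_identity(self, seed):
        # algebraic identity: t^2 == one-way F on two groups
        from scipy.stats import f_oneway, ttest_ind

        rng = np.random.default_rng(seed)
        d = make_design(["A"] * 5 + ["B"] * 5)
        X = rng.normal(size=(10, 8))
        p = univariate_tests(X, d, "group")
        t = ttest_ind(X[:5], X[5:], axis=0, equal_var=True)
        f = f_oneway(X[:5], X[5:], axis=0)
        np.testing.assert_allclose(t.statistic**2, f.statistic, rtol=1e-9)
        np.testing.assert_allclose(p, f.pvalue, rtol=1e-9)

    def test_three_group_anova(self, rng):
        d = make_design(["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        X = rng.normal(size=(12, 5))
        X[8:, 0] += 5.0
        p = univariate_tests(X, d, "group")
        assert p[0] < 0.01
        assert np.all((0 < p) & (p <= 1))

    def test_planted_markers_small_p(self):
        from ascakit.synthetic import SyntheticConfig, generate_feature_dataset

        cfg = SyntheticConfig(
            n_per_group=10, n_variables=60, n_markers=10, effect_size=3.0,
            n_internal_standards=0, seed=17,
        )
        ds = generate_feature_dataset(cfg)
        X = np.log(ds.features.values)
        p = univariate_tests(X, ds.design, "group")
        assert np.median(p[:10]) < 0.01

    def test_small_level_error(self, rng):
        d = make_design(["A", "B", "B"])
        with pytest.raises(DesignError):
            univariate_tests(rng.normal(size=(3, 2)), d, "group")


class TestBhAdjust:
    def test_hand_stepup_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 6), [0.2] * 6)

    def test_validation(self):
        with pytest.raises(ConfigurationError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone(self, p):
        # note: step-up BH is NOT idempotent in general (e.g. [1.0, 0.25]
        # adjusts to [1.0, 0.5] and again to [1.0, 1.0]), so only the
        # monotonicity property is asserted
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_against_statsmodels_oracle(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)


class TestOverfittingGuard:
    def test_permuted_labels_drop_recall_to_chance(self, marker_dataset):
        from ascakit.compare import select_top_k

        ds = marker_dataset
        X = autoscale(
            normalize(ds.features, ds.design).drop_internal_standards().values
        )
        ids = ds.features.drop_internal_standards().variable_ids
        rng = np.random.default_rng(0)
        classes = list(ds.design.factors["group"])
        k = len(ds.truth_markers)
        recalls = []
        for _ in range(10):
            rng.shuffle(classes)
            model = fit_plsda(X, classes, n_latent=2)
            sel = select_top_k(vip_scores(model), ids, "plsda_vip", k=k)
            recalls.append(len(sel.top_k & ds.truth_markers) / k)
        # chance level is k / p = 15/120; true labels give ~1.0
        assert np.mean(recalls) < 0.5
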