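"""Split contract, preprocessing, learners, evaluation and importances."""

import math

import numpy as np
import pandas as pd
import pytest

import codonlife as cl
from codonlife.predict import (
    DEFAULT_GRIDS,
    GreedyForwardBackward,
    group_of_feature,
    learning_curve,
)


def _toy_matrix(rng, n=300, p=10):
    ids = [f"p{i}" for i in range(n)]
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"f{j}" for j in range(p)], index=ids)
    return X


@pytest.fixture
def quick_spec():
    return cl.SplitSpec(seed=0, folds=5, repeats=2)


class TestSplit:
    def test_1000_ids_split_200_800(self):
        split = cl.make_split([f"p{i}" for i in range(1000)], cl.SplitSpec(seed=1))
        assert len(split.test_ids) == 200
        assert len(split.traincv_ids) == 800

    def test_partition_disjoint_exhaustive_balanced(self):
        ids = [f"p{i}" for i in range(437)]
        split = cl.make_split(ids, cl.SplitSpec(seed=3))
        assert set(split.test_ids) | set(split.traincv_ids) == set(ids)
        assert not set(split.test_ids) & set(split.traincv_ids)
        for rep in range(split.spec.repeats):
            sizes = np.bincount(split.fold_labels[rep], minlength=10)
            assert sizes.max() - sizes.min() <= 1

    def test_same_seed_identical(self):
        ids = [f"p{i}" for i in range(100)]
        a = cl.make_split(ids, cl.SplitSpec(seed=7))
        b = cl.make_split(ids, cl.SplitSpec(seed=7))
        assert a.test_ids == b.test_ids
        assert np.array_equal(a.fold_labels, b.fold_labels)

    def test_too_few_ids(self):
        with pytest.raises(ValueError):
            cl.make_split(["a", "b"], cl.SplitSpec())


class TestPreprocessor:
    def test_center_scale_on_train(self, rng):
        X = _toy_matrix(rng)
        prep = cl.Preprocessor(filter=False).fit(X)
        Z = prep.transform(X)
        assert np.allclose(Z.mean(), 0, atol=1e-10)
        assert np.allclose(Z.std(ddof=0), 1, atol=1e-10)

    def test_transform_on_unseen_data_not_centered(self, rng):
        X = _toy_matrix(rng, n=200)
        prep = cl.Preprocessor(filter=False).fit(X.iloc[:100])
        Z_test = prep.transform(X.iloc[100:] + 0.5)
        assert abs(Z_test.mean().mean()) > 0.1

    def test_duplicate_column_removed(self, rng):
        X = _toy_matrix(rng, p=4)
        X["dup"] = X["f0"]
        prep = cl.Preprocessor(filter=True).fit(X)
        kept = set(prep.kept_columns)
        assert len({"f0", "dup"} & kept) == 1

    def test_linear_combination_removed(self, rng):
        X = _toy_matrix(rng, p=4)
        X["combo"] = X["f0"] + 2 * X["f1"]
        prep = cl.Preprocessor(filter=True).fit(X)
        assert len(prep.kept_columns) == 4

    def test_all_constant_matrix_raises(self):
        X = pd.DataFrame({"a": [1.0] * 10, "b": [2.0] * 10})
        with pytest.raises(ValueError):
            cl.Preprocessor().fit(X)


class TestTuneAndFit:
    def test_noiseless_linear_recovered(self, rng, quick_spec):
        X = _toy_matrix(rng)
        y = pd.Series(2 * X["f0"].to_numpy() - X["f3"].to_numpy(), index=X.index)
        split = cl.make_split(list(X.index), quick_spec)
        tuned = cl.tune_and_fit(X, y, split, "elastic_linear")
        assert tuned.rmse_cv < 0.01 * y.std()

    def test_greedy_learner_selects_true_support(self, rng, quick_spec):
        X = _toy_matrix(rng, p=15)
        y = pd.Series(3 * X["f2"].to_numpy() + X["f9"].to_numpy(), index=X.index)
        split = cl.make_split(list(X.index), quick_spec)
        tuned = cl.tune_and_fit(X, y, split, "greedy_forward_backward")
        support = {X.columns[j] for j in tuned.estimator.selected_}
        assert support == {"f2", "f9"}
        assert tuned.rmse_cv < 0.01 * y.std()

    def test_ensemble_beats_linear_on_step_function(self, rng, quick_spec):
        X = _toy_matrix(rng, n=400, p=5)
        y = pd.Series(np.where(X["f0"] > 0, 5.0, -5.0)
                      + 0.1 * rng.normal(size=400), index=X.index)
        split = cl.make_split(list(X.index), quick_spec)
        rf = cl.tune_and_fit(X, y, split, "ensemble_trees",
                             grid=[{"max_features": "sqrt"}], n_estimators=100)
        lin = cl.tune_and_fit(X, y, split, "elastic_linear")
        assert rf.rmse_cv < lin.rmse_cv

    def test_pure_noise_cv_rmse_near_response_sd(self, rng, quick_spec):
        X = _toy_matrix(rng, n=500)
        y = pd.Series(rng.normal(size=500), index=X.index)
        split = cl.make_split(list(X.index), quick_spec)
        tuned = cl.tune_and_fit(X, y, split, "elastic_linear")
        assert tuned.rmse_cv == pytest.approx(y.std(), rel=0.1)

    def test_constant_response_rejected(self, rng, quick_spec):
        X = _toy_matrix(rng, n=100)
        y = pd.Series(1.0, index=X.index)
        split = cl.make_split(list(X.index), quick_spec)
        with pytest.raises(ValueError):
            cl.tune_and_fit(X, y, split, "elastic_linear")


class TestEvaluate:
    def _tuned_identity(self, rng, quick_spec):
        X = _toy_matrix(rng, n=200, p=3)
        y = pd.Series(X["f0"].to_numpy(), index=X.index)
        split = cl.make_split(list(X.index), quick_spec)
        tuned = cl.tune_and_fit(X, y, split, "greedy_forward_backward",
                                grid=[{"k_max": 2}])
        return X, y, split, tuned

    def test_perfect_predictions(self, rng, quick_spec):
        X, y, split, tuned = self._tuned_identity(rng, quick_spec)
        rep = cl.evaluate(tuned, X.loc[list(split.test_ids)], y)
        assert rep.rmse_test == pytest.approx(0, abs=1e-9)
        assert rep.r2_test == pytest.approx(1.0)

    def test_constant_offset_predictions(self, rng, quick_spec):
        X, y, split, tuned = self._tuned_identity(rng, quick_spec)
        rep = cl.evaluate(tuned, X.loc[list(split.test_ids)], y + 3.0)
        assert rep.rmse_test == pytest.approx(3.0, abs=1e-9)
        assert rep.r2_test == pytest.approx(1.0)

    def test_r2_is_square_of_r(self, rng, quick_spec):
        X = _toy_matrix(rng, n=200, p=5)
        y = pd.Series(X["f0"].to_numpy() + rng.normal(size=200), index=X.index)
        split = cl.make_split(list(X.index), quick_spec)
        tuned = cl.tune_and_fit(X, y, split, "elastic_linear")
        rep = cl.evaluate(tuned, X.loc[list(split.test_ids)], y)
        assert rep.r2_test == pytest.approx(rep.r_test ** 2, abs=1e-12)

    def test_leaked_test_ids_rejected(self, rng, quick_spec):
        X, y, split, tuned = self._tuned_identity(rng, quick_spec)
        with pytest.raises(ValueError, match="test ids"):
            cl.evaluate(tuned, X.loc[list(split.traincv_ids)[:10]], y)


class TestPercentOfMax:
    @pytest.mark.parametrize("r2,max_r2,expected", [
        (0.17, 0.48, 35),
        (0.21, 0.48, 44),
        (0.3, 0.3, 100),
    ])
    def test_worked_examples(self, r2, max_r2, expected):
        assert cl.percent_of_max(r2, max_r2).percent == expected

    def test_zero_interstudy_rejected(self):
        with pytest.raises(ValueError):
            cl.percent_of_max(0.2, 0.0)


class TestImportances:
    def test_scaled_max_is_100_and_groups_sum(self, rng, quick_spec):
        X = _toy_matrix(rng)
        y = pd.Series(X["f0"].to_numpy() + 0.5 * X["f1"].to_numpy()
                      + 0.1 * rng.normal(size=len(X)), index=X.index)
        split = cl.make_split(list(X.index), quick_spec)
        tuned = cl.tune_and_fit(X, y, split, "elastic_linear")
        imp = cl.importance_table(tuned, X, y)
        assert imp.scaled.max() == 100.0
        assert np.allclose(imp.scaled, 100.0 * (imp.raw / imp.raw.max()))
        member_sum = imp.scaled.groupby(imp.scaled.index.map(group_of_feature)).sum()
        assert np.allclose(imp.grouped.sort_index(), member_sum.sort_index())

    def test_single_feature_model(self, rng, quick_spec):
        X = _toy_matrix(rng, p=6)
        y = pd.Series(4 * X["f2"].to_numpy(), index=X.index)
        split = cl.make_split(list(X.index), quick_spec)
        tuned = cl.tune_and_fit(X, y, split, "greedy_forward_backward",
                                grid=[{"k_max": 1}])
        imp = cl.importance_table(tuned, X, y)
        assert imp.scaled["f2"] == 100.0
        assert (imp.raw.drop("f2") == 0).all()

    def test_planted_ala_asp_dominate_grouped_ranks(self, small_cohort):
        # response driven solely by Ala (+) and Asp (-) composition
        fm = cl.assemble_feature_matrix(small_cohort.records, tier="composition")
        split = cl.make_split(small_cohort.ids, cl.SplitSpec(seed=1, folds=5, repeats=2))
        prep = cl.Preprocessor(filter=False).fit(fm.values.loc[list(split.traincv_ids)])
        X = prep.transform(fm.values.loc[list(split.traincv_ids)])
        y = small_cohort.responses["lifetime"]
        tuned = cl.tune_and_fit(X, y, split, "elastic_linear")
        imp = cl.importance_table(tuned, X, y)
        top2 = set(imp.grouped.sort_values(ascending=False).index[:2])
        assert top2 == {"small_hydrophobic", "negative_polar"}

    def test_feature_grouping(self):
        assert group_of_feature("aa_A") == "small_hydrophobic"
        assert group_of_feature("codon_GAT") == "negative_polar"
        assert group_of_feature("helix_codon_AAA") == "positive"
        assert group_of_feature("gravy") == "other"


class TestFilteringStability:
    def test_filter_on_off_moves_rmse_under_10_percent(self, planted_features,
                                                       planted_cohort):
        y = planted_cohort.responses["lifetime"]
        ids = planted_cohort.ids[:800]
        split = cl.make_split(ids, cl.SplitSpec(seed=2, folds=5, repeats=2))
        reports = {}
        for flag in (True, False):
            prep = cl.Preprocessor(filter=flag)
            prep.fit(planted_features.values.loc[list(split.traincv_ids)])
            Xtr = prep.transform(planted_features.values.loc[list(split.traincv_ids)])
            Xte = prep.transform(planted_features.values.loc[list(split.test_ids)])
            tuned = cl.tune_and_fit(Xtr, y, split, "elastic_linear")
            reports[flag] = cl.evaluate(tuned, Xte, y)
        a, b = reports[True].rmse_test, reports[False].rmse_test
        assert abs(a - b) / b < 0.10


class TestLearningCurve:
    def test_noiseless_errors_shrink(self, rng, quick_spec):
        X = _toy_matrix(rng, n=400, p=5)
        y = pd.Series(X["f0"].to_numpy(), index=X.index)
        split = cl.make_split(list(X.index), quick_spec)
        curve = learning_curve(X, y, split, "elastic_linear", sizes=[50, 150, 300],
                               params={"alpha": 1e-4, "l1_ratio": 0.5})
        assert curve["rmse_cv"].iloc[-1] < 0.05 * y.std()

    def test_pure_noise_cv_near_sd(self, rng, quick_spec):
        X = _toy_matrix(rng, n=400, p=5)
        y = pd.Series(rng.normal(size=400), index=X.index)
        split = cl.make_split(list(X.index), quick_spec)
        curve = learning_curve(X, y, split, "elastic_linear", sizes=[100, 300])
        assert curve["rmse_cv"].iloc[-1] == pytest.approx(1.0, rel=0.15)

    def test_size_below_folds_rejected(self, rng, quick_spec):
        X = _toy_matrix(rng, n=100, p=3)
        y = pd.Series(rng.normal(size=100), index=X.index)
        split = cl.make_split(list(X.index), quick_spec)
        with pytest.raises(ValueError):
            learning_curve(X, y, split, "elastic_linear", sizes=[2, 50])


class TestGreedyForwardBackward:
    def test_backward_step_removes_stale_feature(self, rng):
        # f2 = f0 + f1 almost exactly; greedy may pick f2 first but should
        # still end with a near-perfect sparse fit
        n = 200
        f0, f1 = rng.normal(size=n), rng.normal(size=n)
        X = np.column_stack([f0, f1, f0 + f1 + 1e-6 * rng.normal(size=n),
                             rng.normal(size=n)])
        y = 2 * f0 - 3 * f1
        est = GreedyForwardBackward(k_max=3).fit(X, y)
        pred = est.predict(X)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 0.01 * y.std()
        assert len(est.selected_) <= 3
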