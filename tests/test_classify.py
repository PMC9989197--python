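"""Feature selection, repeated cross-validation, importances, controls
and misclassification tracking."""

import numpy as np
import pandas as pd
import pytest

from abaffinity import classify
from abaffinity.classify import (
    AffinityClassifier,
    CVConfig,
    CVReport,
    anova_f_select,
    anova_f_statistics,
    combined_select,
    feature_affinity_correlations,
    feature_importances,
    randomization_control,
    run_cv,
    track_misclassified,
)
from abaffinity.synthetic_data import synthetic_classification_table


def _two_group_f(x, y):
    """Closed-form one-way ANOVA F for two groups."""
    g0, g1 = x[y == 0], x[y == 1]
    grand = x.mean()
    ssb = len(g0) * (g0.mean() - grand) ** 2 + len(g1) * (g1.mean() - grand) ** 2
    ssw = ((g0 - g0.mean()) ** 2).sum() + ((g1 - g1.mean()) ** 2).sum()
    return (ssb / 1) / (ssw / (len(x) - 2))


@pytest.fixture
def separable_table(rng):
    n = 60
    y = np.array([0, 1] * (n // 2))
    X = pd.DataFrame({
        "signal": y * 10.0 + rng.normal(scale=0.1, size=n),
        "noise_a": rng.normal(size=n),
        "noise_b": rng.normal(size=n),
        "constant": np.ones(n),
    }, index=[f"c{i}" for i in range(n)])
    labels = np.where(y == 1, "high", "low")
    return X, labels


class TestAnovaSelect:
    def test_perfect_separator_ranked_first(self, separable_table):
        X, labels = separable_table
        assert anova_f_select(X, labels, 2)[0] == "signal"

    def test_constant_features_rank_last_deterministically(self, separable_table):
        X, labels = separable_table
        sel = anova_f_select(X, labels, 4)
        assert sel[-1] == "constant"
        X2 = X.assign(aaa_const=1.0, zzz_const=2.0)
        sel2 = anova_f_select(X2, labels, 6)
        assert sel2[-3:] == ["aaa_const", "constant", "zzz_const"]  # name order

    def test_single_class_labels_error(self, separable_table):
        X, _ = separable_table
        with pytest.raises(ValueError, match="both classes"):
            anova_f_select(X, ["high"] * len(X), 2)

    def test_matches_closed_form(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        X = pd.DataFrame(rng.normal(size=(40, 6)),
                         columns=[f"f{i}" for i in range(6)])
        F = anova_f_statistics(X, np.where(y == 1, "high", "low"))
        for col in X.columns:
            assert F[col] == pytest.approx(_two_group_f(X[col].to_numpy(), y))


class TestCombinedSelect:
    def test_eight_sets_give_sixteen(self, rng):
        y = np.array(["high", "low"] * 20)
        tables = {
            f"set{s}": pd.DataFrame(rng.normal(size=(40, 5)),
                                    columns=[f"set{s}_f{i}" for i in range(5)])
            for s in range(8)
        }
        sel = combined_select(tables, y)
        assert len(sel) == 16
        for s in range(8):   # feature-set order preserved
            assert all(n.startswith(f"set{s}_") for n in sel[2 * s:2 * s + 2])

    def test_duplicate_names_across_sets_error(self, rng):
        y = np.array(["high", "low"] * 5)
        t = pd.DataFrame(rng.normal(size=(10, 2)), columns=["x", "y"])
        with pytest.raises(ValueError, match="duplicate feature names"):
            combined_select({"a": t, "b": t.copy()}, y)


class TestRunCV:
    def test_separable_data_reaches_auc_one(self, separable_table):
        X, labels = separable_table
        cfg = CVConfig(n_repeats=2, n_folds=5, selector_k=2, seed=0)
        rep = run_cv(X, labels, cfg)
        assert rep.median_auc == 1.0
        assert rep.median_f1 == 1.0

    def test_deterministic_given_seed(self, separable_table):
        X, labels = separable_table
        X = X + np.random.default_rng(5).normal(scale=2, size=X.shape)
        cfg = CVConfig(n_repeats=1, n_folds=5, selector_k=3, seed=7)
        r1 = run_cv(X, labels, cfg)
        r2 = run_cv(X, labels, cfg)
        assert r1.fold_aucs.tolist() == r2.fold_aucs.tolist()
        assert r1.fold_f1s.tolist() == r2.fold_f1s.tolist()
        assert r1.importances.equals(r2.importances)

    def test_fold_safe_selection_never_sees_heldout_rows(self, separable_table, monkeypatch):
        """Data-access trace: in fold-safe mode every selection call
        receives strictly fewer rows than the table; in full-data mode the
        single pre-CV call sees all of them."""
        X, labels = separable_table
        calls = []
        orig = classify.anova_f_select

        def spy(table, y, k):
            calls.append(len(table))
            return orig(table, y, k)

        monkeypatch.setattr(classify, "anova_f_select", spy)
        cfg = CVConfig(n_repeats=1, n_folds=5, selector_k=2, seed=0)
        run_cv(X, labels, cfg)
        assert calls and all(n < len(X) for n in calls)

        calls.clear()
        run_cv(X, labels, CVConfig(n_repeats=1, n_folds=5, selector_k=2,
                                   seed=0, full_data_selection=True))
        assert calls == [len(X)]

    def test_metrics_agree_across_classifiers_on_separable_data(self, separable_table):
        X, labels = separable_table
        for kind in ("xgboost", "random_forest", "svc", "mlp"):
            cfg = CVConfig(n_repeats=1, n_folds=5, selector_k=1, seed=0,
                           classifier_kind=kind)
            assert run_cv(X, labels, cfg).median_auc == 1.0


class TestRandomizationControl:
    def test_identity_permutation_reproduces_run_cv(self, separable_table):
        X, labels = separable_table
        cfg = CVConfig(n_repeats=1, n_folds=5, selector_k=2, seed=3)
        assert randomization_control(X, labels, cfg, permute=False) == \
            run_cv(X, labels, cfg).median_auc

    def test_shuffled_labels_destroy_signal(self):
        table, labels, _ = synthetic_classification_table(
            n_complexes=100, seed=5)
        cfg = CVConfig(n_repeats=5, n_folds=10, selector_k=10, seed=5)
        auc = randomization_control(table, labels, cfg)
        assert 0.3 < auc < 0.65  # wide band for a quick 50-fold check
        assert run_cv(table, labels, cfg).median_auc > auc


class TestImportances:
    def test_single_informative_feature_dominates(self, separable_table):
        X, labels = separable_table
        cfg = CVConfig(n_repeats=1, n_folds=5, selector_k=3, seed=0)
        rep = run_cv(X, labels, cfg)
        imp = feature_importances(rep)
        assert imp.index[0] == "signal"
        assert imp["importance"].sum() == pytest.approx(1.0)
        assert imp["importance"]["signal"] > 0.9

    def test_non_tree_classifier_has_no_importances(self, separable_table):
        X, labels = separable_table
        cfg = CVConfig(n_repeats=1, n_folds=5, selector_k=2, seed=0,
                       classifier_kind="svc")
        rep = run_cv(X, labels, cfg)
        with pytest.raises(ValueError, match="no importances"):
            feature_importances(rep)


class TestTrackMisclassified:
    def _report(self, rates):
        return CVReport(np.array([]), np.array([]), 0.5, 0.5,
                        pd.Series(dtype=float), pd.Series(rates))

    def test_thresholds(self):
        ids = ["a", "b", "c"]
        reports = {}
        for s in range(9):
            rates = pd.Series({"a": 1.0,                  # always wrong
                               "b": 0.9 if s < 6 else 0.1,  # only 6 sets
                               "c": 0.0})
            reports[f"set{s}"] = self._report(rates)
        assert track_misclassified(reports) == ["a"]

    def test_planted_outlier_flagged_end_to_end(self):
        """A complex with an inverted label is recurrently misclassified
        across feature-set classifiers."""
        rng = np.random.default_rng(8)
        n = 60
        y = np.array(["high", "low"] * (n // 2))
        ids = [f"c{i}" for i in range(n)]
        reports = {}
        for s in range(9):
            X = pd.DataFrame(
                {"f": (y == "high") * 5.0 + rng.normal(scale=0.2, size=n),
                 "g": rng.normal(size=n)}, index=ids)
            y_bad = y.copy()
            y_bad[0] = "low" if y[0] == "high" else "high"  # inverted label
            cfg = CVConfig(n_repeats=2, n_folds=5, selector_k=1, seed=s)
            reports[f"set{s}"] = run_cv(X, y_bad, cfg)
        assert track_misclassified(reports) == ["c0"]


class TestCorrelations:
    def test_feature_equal_to_affinity_has_unit_r(self, rng):
        aff = rng.normal(9, 1, 30)
        X = pd.DataFrame({"mirror": aff, "noise": rng.normal(size=30),
                          "flat": np.ones(30)})
        corr, constant = feature_affinity_correlations(X, aff)
        assert corr.loc["mirror", "neg_log10_kd"] == pytest.approx(1.0)
        assert constant == ["flat"]
        assert (corr.loc["flat"].drop("flat") == 0).all()
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)

    def test_orthogonal_noise_near_zero(self, rng):
        n = 4000
        X = pd.DataFrame({"noise": rng.normal(size=n)})
        corr, _ = feature_affinity_correlations(X, rng.normal(9, 1, n))
        assert abs(corr.loc["noise", "neg_log10_kd"]) < 0.05
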