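"""Feature tables, ROC/confusion arithmetic, OOB grid search and importance."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import macroflim as mf
from macroflim.classification import (
    PREDICTORS,
    RFSearchGrid,
    variable_importance,
)
from macroflim.errors import ClassCoverageError, DomainError, StratificationError

SMALL_GRID = RFSearchGrid(ntree_candidates=(50, 100))


def brute_force_auc(scores, labels, positive="M1"):
    """Pairwise-comparison oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def feature_frame(n_per_class, sep, seed, donor="A", treatment="FCCP"):
    """Two-class Gaussian feature rows with a configurable class separation
    (in within-class SDs) on every predictor."""
    rng = np.random.default_rng(seed)
    rows = []
    for pheno, shift in (("M1", 0.0), ("M2", sep)):
        for _ in range(n_per_class):
            base = rng.normal(shift, 1.0, size=len(PREDICTORS))
            row = dict(zip(PREDICTORS, base))
            row.update(
                donor=donor, phenotype=pheno, treatment=treatment,
                field_id=0, cell_id=len(rows), alpha1=0.3, good=True,
            )
            rows.append(row)
    return pd.DataFrame(rows)


class TestRocAuc:
    def test_perfect_and_inverted_rankings(self):
        labels = ["M1", "M1", "M2", "M2"]
        assert mf.roc_auc([0.9, 0.8, 0.2, 0.1], labels) == 1.0
        assert mf.roc_auc([0.1, 0.2, 0.8, 0.9], labels) == 0.0

    def test_worked_pairwise_example(self):
        scores = [0.9, 0.4, 0.8, 0.2]
        labels = ["M1", "M1", "M2", "M2"]
        assert mf.roc_auc(scores, labels) == pytest.approx(0.75)
        assert brute_force_auc(scores, labels) == pytest.approx(0.75)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_equals_brute_force_on_random_instances(self, data):
        n = data.draw(st.integers(min_value=2, max_value=50))
        labels = data.draw(
            st.lists(st.sampled_from(["M1", "M2"]), min_size=n, max_size=n).filter(
                lambda ls: len(set(ls)) == 2
            )
        )
        # coarse grid of scores encourages ties
        scores = data.draw(
            st.lists(
                st.integers(min_value=0, max_value=10), min_size=n, max_size=n
            )
        )
        scores = [s / 10 for s in scores]
        assert mf.roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            mf.roc_auc([0.1, 0.9], ["M1", "M1"])


class TestConfusionCounts:
    def test_all_correct_has_no_errors(self):
        tp, fp, fn, tn = mf.confusion_counts(
            [0.9, 0.8, 0.1, 0.2], ["M1", "M1", "M2", "M2"]
        )
        assert (tp, fp, fn, tn) == (2, 0, 0, 2)

    def test_scores_at_threshold_count_positive(self):
        tp, fp, fn, tn = mf.confusion_counts([0.5, 0.5], ["M1", "M2"])
        assert (tp, fp, fn, tn) == (1, 1, 0, 0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0, 1), st.sampled_from(["M1", "M2"])),
            min_size=1,
            max_size=40,
        )
    )
    def test_counts_conserve_rows(self, pairs):
        scores = [p[0] for p in pairs]
        labels = [p[1] for p in pairs]
        counts = mf.confusion_counts(scores, labels)
        assert sum(counts) == len(pairs)
        brute = (
            sum(1 for s, l in pairs if s >= 0.5 and l == "M1"),
            sum(1 for s, l in pairs if s >= 0.5 and l == "M2"),
            sum(1 for s, l in pairs if s < 0.5 and l == "M1"),
            sum(1 for s, l in pairs if s < 0.5 and l == "M2"),
        )
        assert counts == brute


class TestFeatureTable:
    def test_alpha1_dropped_from_predictors(self):
        df = feature_frame(10, 2.0, seed=1)
        X, y, predictors, _ = mf.build_feature_table(df)
        assert "alpha1" not in predictors
        assert X.shape == (20, 5)

    def test_alpha1_kept_when_requested(self):
        df = feature_frame(10, 2.0, seed=1)
        _, _, predictors, _ = mf.build_feature_table(df, drop_collinear=False)
        assert "alpha1" in predictors

    def test_bad_fits_excluded(self):
        df = feature_frame(10, 2.0, seed=2)
        df.loc[:4, "good"] = False
        X, *_ = mf.build_feature_table(df)
        assert X.shape[0] == 15

    def test_single_class_rejected(self):
        df = feature_frame(10, 2.0, seed=3)
        with pytest.raises(ClassCoverageError):
            mf.build_feature_table(df[df.phenotype == "M1"])


class TestZscore:
    def test_columns_standardised(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(5, 3, size=(40, 3)), columns=list("abc"))
        z = mf.zscore_matrix(df)
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=0), 1, atol=1e-12)

    def test_two_row_column_under_population_sd(self):
        z = mf.zscore_matrix(pd.DataFrame({"a": [1.0, 3.0]}))
        np.testing.assert_allclose(z["a"], [-1.0, 1.0])

    def test_constant_column_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="zero variance"):
            z = mf.zscore_matrix(pd.DataFrame({"a": [2.0, 2.0, 2.0], "b": [1.0, 2.0, 3.0]}))
        assert (z["a"] == 0).all()

    def test_single_row_rejected(self):
        with pytest.raises(DomainError):
            mf.zscore_matrix(pd.DataFrame({"a": [1.0]}))


class TestSplit:
    def test_stratified_75_25(self):
        df = feature_frame(50, 1.0, seed=4)
        train, test = mf.split_train_test(df, seed=0)
        assert len(train) == 75 and len(test) == 25
        for part in (train, test):
            counts = part.phenotype.value_counts()
            assert abs(counts["M1"] - counts["M2"]) <= 1

    def test_same_seed_reproduces_split(self):
        df = feature_frame(20, 1.0, seed=5)
        t1, _ = mf.split_train_test(df, seed=9)
        t2, _ = mf.split_train_test(df, seed=9)
        assert list(t1.index) == list(t2.index)

    def test_tiny_class_rejected(self):
        df = feature_frame(10, 1.0, seed=6)
        df = pd.concat([df[df.phenotype == "M1"], df[df.phenotype == "M2"].head(1)])
        with pytest.raises(StratificationError):
            mf.split_train_test(df)


class TestOobGridSearch:
    def test_separable_classes_reach_low_oob_error(self):
        df = feature_frame(18, 5.0, seed=7)
        X, y, predictors, _ = mf.build_feature_table(df)
        _, rep = mf.train_rf_oob_grid(X, y, SMALL_GRID, seed=0)
        assert rep.oob_error <= 5.0
        assert rep.roc_auc >= 0.95

    def test_permuted_labels_near_chance(self):
        df = feature_frame(100, 3.0, seed=8)
        X, y, *_ = mf.build_feature_table(df)
        rng = np.random.default_rng(0)
        _, rep = mf.train_rf_oob_grid(X, rng.permutation(y), SMALL_GRID, seed=0)
        assert 35.0 <= rep.oob_error <= 65.0

    def test_selected_hyperparameters_come_from_grid(self):
        df = feature_frame(15, 2.0, seed=9)
        X, y, *_ = mf.build_feature_table(df)
        grid = RFSearchGrid(ntree_candidates=(50, 100), mtry_candidates=(1, 3))
        _, rep = mf.train_rf_oob_grid(X, y, grid, seed=1)
        assert rep.ntree in grid.ntree_candidates
        assert rep.mtry in grid.mtry_candidates
        assert sum(rep.confusion) == rep.n_rows

    def test_degenerate_labels_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ClassCoverageError):
            mf.train_rf_oob_grid(X, np.array(["M1"] * 10), SMALL_GRID)


class TestVariableImportance:
    def test_informative_predictor_ranks_first_noise_near_zero(self):
        rng = np.random.default_rng(12)
        n = 160
        y = np.array(["M1"] * (n // 2) + ["M2"] * (n // 2))
        X = rng.normal(0, 1, size=(n, 4))
        X[:, 2] += np.where(y == "M1", 0.0, 3.0)  # the only signal
        clf, rep = mf.train_rf_oob_grid(
            X, y, SMALL_GRID, seed=0, predictor_names=["n1", "n2", "sig", "n3"]
        )
        imp = rep.importance
        assert imp["mda"].idxmax() == "sig"
        assert imp["mdg"].idxmax() == "sig"
        for noise in ("n1", "n2", "n3"):
            assert abs(imp.loc[noise, "mda"]) < 3 * imp.loc[noise, "mda_se"] + 1e-9

    def test_importance_covers_training_predictors(self):
        df = feature_frame(12, 2.0, seed=13)
        X, y, predictors, _ = mf.build_feature_table(df)
        _, rep = mf.train_rf_oob_grid(
            X, y, SMALL_GRID, seed=0, predictor_names=predictors
        )
        assert list(rep.importance.index) == list(predictors)

    def test_model_without_oob_rejected(self):
        from sklearn.ensemble import RandomForestClassifier

        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.array(["M1", "M2"] * 10)
        clf = RandomForestClassifier(n_estimators=10, random_state=0).fit(X, y)
        with pytest.raises(DomainError):
            variable_importance(clf, X, y)


class TestUmap:
    def test_deterministic_and_separates_constructed_clusters(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.1, size=(40, 5)) + np.array([1, 0, 0, 0, 0])
        b = rng.normal(0, 0.1, size=(40, 5)) + np.array([0, 0, 0, 1, 1])
        X = np.vstack([a, b])
        X[1] = X[0]  # exact duplicate row
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c1 = mf.umap_embed(X, seed=3)
            c2 = mf.umap_embed(X, seed=3)
        np.testing.assert_array_equal(c1, c2)
        from sklearn.metrics import silhouette_score

        labels = np.array([0] * 40 + [1] * 40)
        assert silhouette_score(c1, labels) > 0.5
        # duplicated rows embed near-coincidentally relative to cluster scale
        d_dup = np.hypot(*(c1[0] - c1[1]))
        spread = np.hypot(*(c1[:40].std(axis=0)))
        assert d_dup < 10 * spread + 1.0

    def test_too_few_rows_rejected(self):
        with pytest.raises(DomainError):
            mf.umap_embed(np.zeros((3, 5)), seed=0)


class TestDonorModels:
    def test_reports_per_donor_with_effect_size_ordering(self):
        strong = feature_frame(40, 4.0, seed=20, donor="D")
        weak = feature_frame(40, 0.3, seed=21, donor="B")
        rows = pd.concat([strong, weak], ignore_index=True)
        reports = mf.run_donor_models(rows, SMALL_GRID, seed=2)
        assert set(reports) == {"B", "D"}
        assert reports["D"].roc_auc >= 0.9
        assert reports["B"].roc_auc < reports["D"].roc_auc
        for rep in reports.values():
            assert rep.ntree and rep.mtry
            assert 0 <= rep.oob_error <= 100
            assert sum(rep.confusion) == rep.n_rows * 0.25

    def test_donor_missing_a_class_skipped(self):
        ok = feature_frame(20, 3.0, seed=22, donor="A")
        broken = feature_frame(20, 3.0, seed=23, donor="X")
        broken = broken[broken.phenotype == "M1"]
        reports = mf.run_donor_models(
            pd.concat([ok, broken], ignore_index=True), SMALL_GRID, seed=0
        )
        assert set(reports) == {"A"}
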