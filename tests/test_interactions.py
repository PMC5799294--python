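"""Interaction labelling, balancing, cross-validation, thresholds, sharing."""

import numpy as np
import pandas as pd
import pytest

from txdecomp.interactions import (
    interaction_sharing,
    label_pairs,
    optimize_thresholds,
    predict_celltypes,
    similarity_1l1,
    smote_balance,
    subsample_np,
    train_cv,
    evaluate,
)


@pytest.fixture()
def small_pairs():
    return pd.DataFrame({"bait": [1, 1, 1], "target": [10, 20, 30], "distance": [9, 19, 29]})


class TestLabelPairs:
    def test_cutoff_inclusive_and_absent_negative(self, small_pairs):
        table = pd.DataFrame({"bait": [1, 1], "target": [10, 20], "score": [3.0, 2.99]})
        labels = label_pairs(small_pairs, table, cutoff=3.0)
        np.testing.assert_array_equal(labels, [1, 0, 0])

    def test_duplicates_keep_highest_score(self, small_pairs):
        table = pd.DataFrame({"bait": [1, 1], "target": [10, 10], "score": [1.0, 5.0]})
        with pytest.warns(UserWarning, match="duplicate"):
            labels = label_pairs(small_pairs, table, cutoff=3.0)
        np.testing.assert_array_equal(labels, [1, 0, 0])


class TestSubsampleNP:
    def test_twenty_to_one_when_abundant(self):
        f = pd.DataFrame({"distance": [7] * 205})
        y = np.array([1] * 5 + [0] * 200)
        idx = subsample_np(f, y, ratio=20, seed=0)
        assert (y[idx] == 1).sum() == 5
        assert (y[idx] == 0).sum() == 100

    def test_with_replacement_when_scarce(self):
        f = pd.DataFrame({"distance": [7] * 65})
        y = np.array([1] * 5 + [0] * 60)
        idx = subsample_np(f, y, ratio=20, seed=0)
        assert (y[idx] == 0).sum() == 100  # sampled with replacement beyond 60

    def test_deterministic(self):
        f = pd.DataFrame({"distance": np.repeat([7, 9], 50)})
        y = np.tile([1, 0, 0, 0, 0], 20)
        a = subsample_np(f, y, seed=3)
        b = subsample_np(f, y, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            subsample_np(pd.DataFrame({"distance": [7]}), np.array([0]))


class TestSmote:
    def test_bookkeeping_ten_positives(self):
        """percOver=200/percUnder=150: 10 positives -> 30:30 stratum."""
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (300, 4))
        y = np.array([1] * 10 + [0] * 290)
        d = np.full(300, 12)
        Xb, yb, origin, db = smote_balance(X, y, d, seed=0)
        assert (yb == 1).sum() == 30
        assert (yb == 0).sum() == 30
        assert (origin == -1).sum() == 20  # synthetic rows

    def test_exact_one_to_one_at_every_stratum(self):
        rng = np.random.default_rng(1)
        d = np.repeat([10, 20, 30], 100)
        y = np.concatenate([[1] * 5 + [0] * 95, [1] * 8 + [0] * 92, [1] * 3 + [0] * 97])
        X = rng.normal(0, 1, (300, 3))
        Xb, yb, origin, db = smote_balance(X, y, d, seed=0)
        for dist, n_pos in zip((10, 20, 30), (5, 8, 3)):
            sel = db == dist
            assert (yb[sel] == 1).sum() == (yb[sel] == 0).sum() == 3 * n_pos

    def test_synthetic_rows_interpolate_between_positives(self):
        rng = np.random.default_rng(2)
        X = np.concatenate([rng.normal(5, 0.1, (10, 2)), rng.normal(-5, 0.1, (50, 2))])
        y = np.array([1] * 10 + [0] * 50)
        d = np.full(60, 8)
        Xb, yb, origin, _ = smote_balance(X, y, d, seed=0)
        synth = Xb[(origin == -1)]
        lo = X[:10].min(axis=0)
        hi = X[:10].max(axis=0)
        assert np.all(synth >= lo - 1e-9) and np.all(synth <= hi + 1e-9)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (100, 3))
        y = np.array([1] * 10 + [0] * 90)
        d = np.full(100, 8)
        a = smote_balance(X, y, d, seed=5)[0]
        b = smote_balance(X, y, d, seed=5)[0]
        np.testing.assert_array_equal(a, b)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            smote_balance(np.ones((5, 2)), np.zeros(5, dtype=int), np.full(5, 8))


class TestTrainCV:
    def test_every_pair_heldout_exactly_once(self, planted_universe):
        model = train_cv(
            planted_universe["X"].iloc[:600], planted_universe["y"][:600],
            n_folds=5, n_trees=50, seed=0,
        )
        counts = np.bincount(model.fold_of, minlength=5)
        assert counts.sum() == 600
        assert np.all(np.isfinite(model.heldout_probabilities))

    def test_planted_signal_recovered(self, planted_universe):
        from sklearn.metrics import roc_auc_score

        model = train_cv(
            planted_universe["X"], planted_universe["y"], n_folds=10, n_trees=200, seed=0
        )
        auc = roc_auc_score(planted_universe["y"], model.heldout_probabilities)
        assert auc >= 0.9

    def test_permuted_labels_are_chance(self, planted_universe):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        y_perm = rng.permutation(planted_universe["y"])
        model = train_cv(planted_universe["X"], y_perm, n_folds=10, n_trees=100, seed=0)
        auc = roc_auc_score(y_perm, model.heldout_probabilities)
        assert 0.45 <= auc <= 0.55


class TestDistanceBandModels:
    def test_one_importance_table_per_nonempty_band(self, planted_universe):
        from txdecomp.interactions import distance_band_models

        X = planted_universe["X"].iloc[:800].reset_index(drop=True)
        y = planted_universe["y"][:800]
        out = distance_band_models(
            X, y, bands=[(5, 25), (25, 50), (50, 200)],
            n_folds=3, n_trees=25, seed=0, importance_repeats=1,
        )
        assert set(out) == {(5, 25), (25, 50), (50, 200)}
        for imp in out.values():
            assert set(imp.index) == set(X.columns)

    def test_empty_band_skipped_with_warning(self, planted_universe):
        from txdecomp.interactions import distance_band_models

        X = planted_universe["X"].iloc[:300].reset_index(drop=True)
        y = planted_universe["y"][:300]
        with pytest.warns(UserWarning, match="skipped"):
            out = distance_band_models(
                X, y, bands=[(500, 600)], n_folds=2, n_trees=10, seed=0
            )
        assert out == {}


class TestThresholds:
    def test_hand_worked_toy(self):
        thr = optimize_thresholds(
            np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]),
            np.array([7, 7, 7, 7]), bands=[(5, 10)],
        )
        assert thr["cutoff"].iloc[0] == pytest.approx(0.205)
        assert thr["f1"].iloc[0] == pytest.approx(1.0)

    def test_all_positive_calls_everything(self):
        thr = optimize_thresholds(
            np.array([0.2, 0.9]), np.array([1, 1]), np.array([7, 7]), bands=[(5, 10)]
        )
        assert thr["cutoff"].iloc[0] == 0.0

    def test_returned_cutoff_is_grid_optimal(self):
        rng = np.random.default_rng(13)
        p = rng.random(300)
        y = (rng.random(300) < p).astype(int)
        d = rng.integers(6, 201, 300)
        thr = optimize_thresholds(p, y, d)
        from sklearn.metrics import f1_score

        for _, row in thr.iterrows():
            if not row["defined"]:
                continue
            sel = (d > row["lo"]) & (d <= row["hi"])
            for c in np.arange(0, 1.0001, 0.005):
                f1 = f1_score(y[sel], p[sel] >= c, zero_division=0)
                assert row["f1"] >= f1 - 1e-12

    def test_band_without_positives_flagged(self):
        thr = optimize_thresholds(
            np.array([0.5]), np.array([0]), np.array([7]), bands=[(5, 10)]
        )
        assert not thr["defined"].iloc[0]


class TestEvaluate:
    def test_perfect_separation(self):
        out = evaluate(np.array([0.9, 0.8, 0.1]), np.array([1, 1, 0]))
        assert out["pooled"]["auc"] == 1.0

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(14)
        p = rng.random(200)
        y = rng.integers(0, 2, 200)
        a = evaluate(p, y)["pooled"]["auc"]
        b = evaluate(np.sqrt(p) ** 3, y)["pooled"]["auc"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_flagged(self):
        out = evaluate(np.array([0.5, 0.6]), np.array([1, 1]))
        assert np.isnan(out["pooled"]["auc"]) and out["pooled"]["single_class"]

    def test_per_chromosome_blocks(self):
        out = evaluate(
            np.array([0.9, 0.1, 0.8, 0.2]), np.array([1, 0, 1, 0]),
            chroms=np.array(["chr1", "chr1", "chr2", "chr2"]),
        )
        assert set(out["per_chromosome"]) == {"chr1", "chr2"}


class TestPredictCellTypes:
    def test_probability_is_mean_of_fold_models(self, planted_universe):
        X = planted_universe["X"].iloc[:400]
        y = planted_universe["y"][:400]
        model = train_cv(X, y, n_folds=4, n_trees=30, seed=0)
        thr = optimize_thresholds(model.heldout_probabilities, y, X["distance"].to_numpy())
        tables = {"other": X}
        out = predict_celltypes(model, tables, thr)
        manual = np.mean(
            [m.predict_proba(X.to_numpy())[:, list(m.classes_).index(1)] for m in model.models],
            axis=0,
        )
        np.testing.assert_allclose(out["other"]["probability"].to_numpy(), manual)

    def test_focal_cell_uses_heldout_probabilities(self, planted_universe):
        X = planted_universe["X"].iloc[:400]
        y = planted_universe["y"][:400]
        model = train_cv(X, y, n_folds=4, n_trees=30, seed=0)
        thr = optimize_thresholds(model.heldout_probabilities, y, X["distance"].to_numpy())
        out = predict_celltypes(model, {"focal": X, "other": X}, thr, focal_cell="focal")
        np.testing.assert_array_equal(
            out["focal"]["probability"].to_numpy(), model.heldout_probabilities
        )

    def test_identical_tables_identical_calls(self, planted_universe):
        X = planted_universe["X"].iloc[:300]
        y = planted_universe["y"][:300]
        model = train_cv(X, y, n_folds=3, n_trees=30, seed=0)
        thr = optimize_thresholds(model.heldout_probabilities, y, X["distance"].to_numpy())
        out = predict_celltypes(model, {"a": X, "b": X.copy()}, thr)
        np.testing.assert_array_equal(out["a"]["call"], out["b"]["call"])


class TestSharing:
    def test_similarity_identities(self):
        assert similarity_1l1(np.array([[1, 1], [0, 0], [1, 1]]))[0, 1] == 1.0
        assert similarity_1l1(np.array([[1, 0], [0, 1]]))[0, 1] == 0.0

    def test_hand_example(self):
        B = np.array([[1, 1], [0, 1], [1, 1], [0, 0]])
        assert similarity_1l1(B)[0, 1] == pytest.approx(0.75)

    def test_exact_k_histogram(self):
        calls = {"a": [1, 1, 0], "b": [1, 0, 0], "c": [1, 0, 1]}
        hist, sim = interaction_sharing(calls)
        assert hist[3] == 1 and hist[1] == 2 and hist[2] == 0
        assert sim.loc["a", "a"] == 1.0
        assert sim.equals(sim.T)
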