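"""Feature pruning, near-miss rebalancing, forest training and evaluation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_classification_frame
from routexpose.errors import (
    ClassMissingError,
    InvalidConfigError,
    SchemaError,
    StateError,
    StratificationError,
)
from routexpose.modeling import (
    CorrelationPruner,
    ModeChoiceForest,
    ModelConfig,
    NearMissUndersampler,
    evaluate,
    nearmiss_undersample,
    prune_correlated,
    split,
    train_forest,
    tune_forest,
)


class TestCorrelationPruner:
    def test_identical_columns_one_retained(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=500)})
        kept = CorrelationPruner(0.8).fit(X).retained_features_
        assert "c" in kept and len([c for c in kept if c in ("a", "b")]) == 1

    def test_independent_columns_both_retained(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
        assert CorrelationPruner(0.8).fit(X).retained_features_ == ["a", "b"]

    def test_keep_list_forces_paper_retained_poi_set(self):
        """Six POI columns with pairwise r ~ 0.9: only the four protected
        columns survive, mirroring the retained retail/education/recreation/
        health set."""
        rng = np.random.default_rng(2)
        base = rng.normal(size=3000)
        cols = {}
        names = ["mean_poi_retail", "mean_poi_educational", "mean_poi_recreational",
                 "mean_poi_medical", "mean_poi_public_services", "mean_poi_others"]
        for name in names:
            cols[name] = base + rng.normal(scale=0.32, size=3000)
        cols["distance_m"] = rng.normal(size=3000)
        X = pd.DataFrame(cols)
        corr = X[names].corr().abs().to_numpy()
        assert corr[np.triu_indices(6, 1)].min() > 0.8  # setup is as claimed
        keep = ("mean_poi_retail", "mean_poi_educational", "mean_poi_recreational",
                "mean_poi_medical")
        kept = CorrelationPruner(0.8, keep=keep).fit(X).retained_features_
        assert set(kept) == set(keep) | {"distance_m"}

    def test_constant_column_warned_and_dropped(self):
        X = pd.DataFrame({"a": np.arange(100.0), "b": np.ones(100)})
        with pytest.warns(UserWarning, match="constant"):
            kept = CorrelationPruner(0.8).fit(X).retained_features_
        assert kept == ["a"]

    def test_no_retained_pair_above_threshold(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(2000, 3))
        X = pd.DataFrame({
            "a": z[:, 0], "b": z[:, 0] + 0.1 * z[:, 1], "c": z[:, 1], "d": z[:, 2],
        })
        kept = CorrelationPruner(0.8).fit(X).retained_features_
        sub = X[kept].corr().abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        assert sub.max() <= 0.8


class TestNearMiss:
    def test_counts_equal_minority(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        y = ["car"] * 10 + ["bicycle"] * 4 + ["walk"] * 6
        Xr, yr = nearmiss_undersample(X, y)
        assert yr.value_counts().to_dict() == {"car": 4, "bicycle": 4, "walk": 4}

    def test_minority_rows_unchanged(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"])
        y = ["car"] * 4 + ["bicycle"] * 4 + ["walk"] * 4
        Xr, yr = nearmiss_undersample(X, y)
        pd.testing.assert_frame_equal(Xr, X)  # already balanced: identity

    def test_empty_class_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ClassMissingError):
            nearmiss_undersample(X, ["car", "car"])

    @pytest.mark.parametrize("variant", ["keep-closest", "remove-closest"])
    def test_retained_ids_match_brute_force(self, variant):
        """25-point toy at known coordinates vs an exhaustive distance
        computation."""
        rng = np.random.default_rng(7)
        maj = rng.uniform(0, 10, size=(20, 2))
        mino = rng.uniform(0, 10, size=(5, 2))
        X = pd.DataFrame(np.vstack([maj, mino]), columns=["a", "b"])
        y = ["car"] * 20 + ["walk"] * 5

        sampler = NearMissUndersampler(variant=variant)
        Xr, yr = sampler.fit_resample(X, y)
        got = sorted(i for i in sampler.sample_indices_ if i < 20)

        # brute force on the z-scored copy
        Z = (X - X.mean()) / X.std(ddof=0)
        zmaj, zmin = Z.to_numpy()[:20], Z.to_numpy()[20:]
        scores = []
        for row in zmaj:
            d = np.sort(np.hypot(*(zmin - row).T))
            scores.append(d[:3].mean())
        order = np.argsort(np.array(scores), kind="stable")
        expect = sorted(order[:5]) if variant == "keep-closest" else sorted(order[::-1][:5])
        assert got == list(expect)
        assert (yr == "car").sum() == 5


class TestSplit:
    def frame(self, per_class=50):
        rng = np.random.default_rng(0)
        rows = []
        for mode in ("car", "bicycle", "walk"):
            for _ in range(per_class):
                rows.append({"mode": mode, "x": rng.normal()})
        return pd.DataFrame(rows)

    def test_stratified_partition(self):
        table = self.frame(100)
        train, test = split(table, 0.3, seed=0)
        assert len(train) == 210 and len(test) == 90
        assert sorted(test["mode"].value_counts()) == [30, 30, 30]
        assert set(train.index).isdisjoint(test.index)
        assert len(train) + len(test) == len(table)

    def test_deterministic(self):
        table = self.frame()
        t1 = split(table, 0.3, seed=5)[0]
        t2 = split(table, 0.3, seed=5)[0]
        pd.testing.assert_frame_equal(t1, t2)

    def test_half_split_exact(self):
        table = self.frame(10)
        train, test = split(table, 0.5, seed=1)
        assert sorted(train["mode"].value_counts()) == [5, 5, 5]
        assert sorted(test["mode"].value_counts()) == [5, 5, 5]

    def test_missing_mode_rejected(self):
        table = self.frame().query("mode != 'walk'")
        with pytest.raises(StratificationError):
            split(table, 0.3, seed=0)


class TestTuneAndTrain:
    def test_single_point_grid(self):
        frame = make_classification_frame(300, seed=0)
        cfg = ModelConfig(tree_grid=(50,), max_features_grid=(2,), seed=0)
        (n_trees, mf), grid = tune_forest(frame, cfg)
        assert (n_trees, mf) == (50, 2)
        assert len(grid) == 1

    def test_grid_bookkeeping_and_skip(self):
        frame = make_classification_frame(300, seed=0)  # p = 5 features
        with pytest.warns(UserWarning, match="skipping"):
            cfg = ModelConfig(tree_grid=(20, 40), max_features_grid=(1, 3, 99), seed=0)
            _, grid = tune_forest(frame, cfg)
        assert len(grid) == 2 * 2  # the max_features=99 points are skipped

    def test_selected_beats_majority_baseline(self):
        frame = make_classification_frame(900, seed=1)
        cfg = ModelConfig(tree_grid=(60,), max_features_grid=(1, 2), seed=1)
        _, grid = tune_forest(frame, cfg)
        baseline = frame["mode"].value_counts(normalize=True).max()
        assert grid["cv_accuracy"].max() >= baseline

    def test_vote_fractions_sum_to_one(self):
        frame = make_classification_frame(300, seed=2)
        model = train_forest(frame, 30, "sqrt", seed=0)
        votes = model.vote_fractions(frame.drop(columns=["individual_id", "mode"]))
        assert np.allclose(votes.sum(axis=1), 1.0)
        assert votes.min() >= 0 and votes.max() <= 1

    def test_same_seed_same_predictions(self):
        frame = make_classification_frame(400, seed=3)
        X = frame.drop(columns=["individual_id", "mode"])
        p1 = train_forest(frame, 40, 2, seed=9).predict(X)
        p2 = train_forest(frame, 40, 2, seed=9).predict(X)
        assert (p1 == p2).all()

    def test_separable_data_high_accuracy(self):
        frame = make_classification_frame(3000, seed=4)
        train, test = split(frame, 0.3, seed=4)
        model = train_forest(train, 100, "sqrt", seed=4)
        rep = evaluate(model, test)
        assert rep.accuracy > 0.95

    def test_invalid_tree_count(self):
        frame = make_classification_frame(50, seed=0)
        with pytest.raises(InvalidConfigError):
            train_forest(frame, 0, "sqrt", seed=0)

    def test_unfitted_model_raises(self):
        with pytest.raises(StateError):
            ModeChoiceForest().vote_fractions(pd.DataFrame({"a": [1.0]}))


class TestEvaluate:
    def test_perfect_predictor_diagonal(self):
        # 30 rows in three well-separated clusters: the fitted forest is an
        # exact predictor, so the confusion matrix must be diagonal
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            {
                "individual_id": np.arange(30),
                "x0": np.repeat([0.0, 10.0, 20.0], 10) + rng.uniform(0, 1, 30),
                "x1": rng.normal(size=30),
                "mode": np.repeat(["walk", "bicycle", "car"], 10),
            }
        )
        model = train_forest(frame, 25, "sqrt", seed=5)
        rep = evaluate(model, frame)
        mat = rep.confusion.to_numpy()
        assert rep.accuracy == 1.0
        assert mat.sum() - np.trace(mat) == 0
        assert list(rep.confusion.index) == ["car", "bicycle", "walk"]

    def test_schema_mismatch_rejected(self):
        frame = make_classification_frame(200, seed=6)
        model = train_forest(frame, 10, "sqrt", seed=6)
        bad = frame.rename(columns={"x0": "q0"})
        with pytest.raises(SchemaError):
            evaluate(model, bad)

    def test_matrix_matches_brute_force_tally(self):
        frame = make_classification_frame(600, seed=7)
        train, test = split(frame, 0.3, seed=7)
        model = train_forest(train, 30, "sqrt", seed=7)
        rep = evaluate(model, test)
        pred = model.predict(test.drop(columns=["individual_id", "mode"]))
        true = test["mode"].to_numpy()
        for i, t in enumerate(("car", "bicycle", "walk")):
            for j, q in enumerate(("car", "bicycle", "walk")):
                assert rep.confusion.iloc[i, j] == int(((true == t) & (pred == q)).sum())
        assert rep.accuracy == pytest.approx((pred == true).mean())


class TestStatisticalSanity:
    def test_oob_tracks_heldout_accuracy(self):
        """On clean (non-duplicated) synthetic data the OOB estimate and the
        held-out accuracy agree within 5 points, averaged over 3 seeds."""
        gaps = []
        for seed in (0, 1, 2):
            frame = make_classification_frame(10_000, seed=seed)
            train, test = split(frame, 0.3, seed=seed)
            model = train_forest(train, 60, "sqrt", seed=seed)
            rep = evaluate(model, test)
            gaps.append(abs(model.oob_score_ - rep.accuracy))
        assert np.mean(gaps) < 0.05

    def test_label_permutation_restores_chance(self):
        """Shuffled labels on balanced data leave nothing to learn: held-out
        accuracy returns to 1/3 within 3 points."""
        frame = make_classification_frame(4500, seed=8)
        counts = frame["mode"].value_counts()
        balanced = pd.concat(
            [frame[frame["mode"] == m].head(counts.min()) for m in counts.index]
        )
        rng = np.random.default_rng(8)
        shuffled = balanced.copy()
        shuffled["mode"] = rng.permutation(shuffled["mode"].to_numpy())
        train, test = split(shuffled, 0.3, seed=8)
        model = train_forest(train, 60, "sqrt", seed=8)
        rep = evaluate(model, test)
        assert abs(rep.accuracy - 1 / 3) < 0.03
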