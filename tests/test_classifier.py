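import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from ribocall.classifier import (
    FEATURE_COLUMNS,
    TrainingSpec,
    TranslatedOrfSVM,
    build_sets,
    call_orfs,
    evaluate_roc,
)


class _ScoreModel:
    """Fixed-score stand-in for ROC arithmetic tests."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)

    def predict_proba(self, X):
        return np.column_stack([1 - self.scores, self.scores])


class TestTrainingSpec:
    def test_cutoff_validation(self):
        with pytest.raises(ValueError):
            TrainingSpec(prob_cutoff=1.5)


class TestBuildSets:
    def test_sampling_contract(self, demo_run):
        spec = TrainingSpec(
            n_pos_train=20, n_neg_train=30, n_pos_test=20, n_neg_test=30, seed=1
        )
        train, test = build_sets(demo_run.run.features, spec, demo_run.biotypes)
        assert (train.label == 1).sum() == 20 and (train.label == 0).sum() == 30
        assert (test.label == 1).sum() == 20 and (test.label == 0).sum() == 30

    def test_same_seed_identical_different_seed_not(self, demo_run):
        spec = TrainingSpec(
            n_pos_train=20, n_neg_train=30, n_pos_test=20, n_neg_test=30, seed=5
        )
        t1, _ = build_sets(demo_run.run.features, spec, demo_run.biotypes)
        t2, _ = build_sets(demo_run.run.features, spec, demo_run.biotypes)
        pd.testing.assert_frame_equal(t1, t2)
        spec2 = TrainingSpec(
            n_pos_train=20, n_neg_train=30, n_pos_test=20, n_neg_test=30, seed=6
        )
        t3, _ = build_sets(demo_run.run.features, spec2, demo_run.biotypes)
        assert not t1.equals(t3)

    def test_small_pool_reports_sizes(self, demo_run):
        spec = TrainingSpec(seed=1)  # paper-scale counts exceed the sim pool
        with pytest.raises(ValueError, match="positives"):
            build_sets(demo_run.run.features, spec, demo_run.biotypes)

    def test_negative_pool_composition(self, demo_run):
        from ribocall.classifier import training_pools

        spec = TrainingSpec(n_pos_train=10, n_neg_train=10, n_pos_test=10, n_neg_test=10)
        pos, neg = training_pools(demo_run.run.features, spec, demo_run.biotypes)
        assert (pos.orf_type == "canonical").all()
        for row in neg.itertuples():
            on_short = demo_run.biotypes.get(row.transcript_id) == "short_ncRNA"
            assert on_short or (row.orf_type == "internal" and row.start_codon == "AUG")


class TestEstimatorContract:
    def test_separable_toy_cv_score_perfect(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.05, (40, 3)), rng.normal(1, 0.05, (40, 3))]
        )
        y = np.repeat([0, 1], 40)
        m = TranslatedOrfSVM(random_state=0).fit(X, y)
        assert m.cv_score_ == pytest.approx(1.0)
        assert (m.predict(X) == y).all()

    def test_single_class_raises(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError):
            TranslatedOrfSVM().fit(X, np.zeros(20))

    def test_get_set_params_round_trip(self):
        m = TranslatedOrfSVM(cv=3, random_state=9)
        params = m.get_params()
        assert params["cv"] == 3
        m2 = TranslatedOrfSVM().set_params(**params)
        assert m2.random_state == 9

    def test_probability_row_order_invariance(self, demo_model):
        X = demo_model.test[list(FEATURE_COLUMNS)].to_numpy()
        p = demo_model.model.predict_proba(X)[:, 1]
        perm = np.random.default_rng(1).permutation(len(X))
        p2 = demo_model.model.predict_proba(X[perm])[:, 1]
        np.testing.assert_allclose(p[perm], p2)

    def test_training_reproducible(self, demo_model):
        X = demo_model.train[list(FEATURE_COLUMNS)].to_numpy()
        y = demo_model.train["label"].to_numpy()
        m2 = TranslatedOrfSVM(random_state=11).fit(X, y)
        assert m2.best_params_ == demo_model.model.best_params_
        Xt = demo_model.test[list(FEATURE_COLUMNS)].to_numpy()
        np.testing.assert_allclose(
            m2.predict_proba(Xt), demo_model.model.predict_proba(Xt)
        )


class TestRoc:
    def test_perfect_separation_auc_one(self):
        m = _ScoreModel([0.9, 0.8, 0.2, 0.1])
        r = evaluate_roc(m, np.zeros((4, 3)), [1, 1, 0, 0])
        assert r["auc"] == pytest.approx(1.0)

    def test_constant_scores_auc_half(self):
        m = _ScoreModel([0.5] * 6)
        r = evaluate_roc(m, np.zeros((6, 3)), [1, 1, 1, 0, 0, 0])
        assert r["auc"] == pytest.approx(0.5)

    def test_four_item_pair_counting(self):
        r = evaluate_roc(_ScoreModel([0.9, 0.8, 0.7, 0.1]), np.zeros((4, 3)), [1, 1, 0, 0])
        assert r["auc"] == pytest.approx(1.0)
        r = evaluate_roc(_ScoreModel([0.9, 0.6, 0.7, 0.1]), np.zeros((4, 3)), [1, 1, 0, 0])
        assert r["auc"] == pytest.approx(0.75)

    def test_single_class_test_set_raises(self):
        with pytest.raises(ValueError):
            evaluate_roc(_ScoreModel([0.5, 0.6]), np.zeros((2, 3)), [1, 1])

    def test_auc_equals_mann_whitney_normalisation(self, demo_model):
        X = demo_model.test[list(FEATURE_COLUMNS)].to_numpy()
        y = demo_model.test["label"].to_numpy()
        r = evaluate_roc(demo_model.model, X, y)
        scores = demo_model.model.predict_proba(X)[:, 1]
        u = mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        assert r["auc"] == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()))

    def test_error_rates_at_cutoff(self):
        m = _ScoreModel([0.95, 0.69, 0.71, 0.1])
        r = evaluate_roc(m, np.zeros((4, 3)), [1, 1, 0, 0], cutoff=0.7)
        assert r["fnr_at_cutoff"] == pytest.approx(0.5)
        assert r["fpr_at_cutoff"] == pytest.approx(0.5)


class TestCallOrfs:
    def test_expression_filter_excludes_before_scoring(self, demo_model, demo_run):
        feats = demo_run.run.features
        res = call_orfs(demo_model.model, feats, demo_model.spec)
        called = res.predictions
        assert (called.n_reads > 10).all()
        assert (called.rpkm > 1).all()

    def test_cutoff_boundary(self, demo_model):
        df = pd.DataFrame(
            {
                "transcript_id": ["a", "b"],
                "start": [0, 0],
                "stop": [60, 60],
                "start_codon": ["AUG", "AUG"],
                "orf_type": ["canonical", "canonical"],
                "f1": [0.9, 0.1],
                "f2": [0.05, 0.2],
                "pme": [0.95, 0.1],
                "n_reads": [100, 100],
                "n_codons": [19, 19],
                "rpkm": [50.0, 50.0],
            }
        )

        class Fixed:
            def predict_proba(self, X):
                p = np.array([0.71, 0.69])
                return np.column_stack([1 - p, p])

        res = call_orfs(Fixed(), df, TrainingSpec())
        assert res.predictions.call.tolist() == [True, False]

    def test_representative_selection_collapses_stop_groups(
        self, demo_model, demo_run
    ):
        res = call_orfs(
            demo_model.model,
            demo_run.run.features,
            demo_model.spec,
            orfs=demo_run.run.catalog,
            profiles=demo_run.run.profiles,
        )
        reps = res.predictions[res.predictions.representative]
        # at most one representative per (transcript, stop)
        assert not reps.duplicated(subset=["transcript_id", "stop"]).any()
        assert set(res.summary.index) <= {
            "canonical",
            "truncated",
            "extended",
            "uORF",
            "overlapping_uORF",
            "internal",
            "dORF",
            "noncoding_ORF",
        }


def test_sklearn_pipeline_composition(demo_model):
    """The estimator composes with sklearn pipelines and CV utilities."""
    from sklearn.model_selection import cross_val_score
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    X = demo_model.train[list(FEATURE_COLUMNS)].to_numpy()
    y = demo_model.train["label"].to_numpy()
    pipe = make_pipeline(
        StandardScaler(), TranslatedOrfSVM(C_grid=(1.0,), gamma_grid=(1.0,), cv=3)
    )
    scores = cross_val_score(pipe, X, y, cv=3, scoring="roc_auc")
    assert scores.mean() > 0.9
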