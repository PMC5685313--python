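import numpy as np
import pandas as pd
import pytest

from remission_rank.ann import (AnnModel, _loss_grad, _loss_grad_numpy,
                                encode, encoded_rows, olden_importance,
                                predict_score, train_ann)
from remission_rank.config import StudyConfig
from remission_rank.datatypes import CohortTable, GenotypeMatrix
from remission_rank.evaluation import roc_auc


class TestEncoding:
    def test_dichotomous_maps_to_soft_targets(self, tiny_cohort):
        X, y, enc = encode(tiny_cohort, None, ["insulin_medication"],
                           tiny_cohort.sample_ids)
        assert set(X["insulin_medication"]) == {0.05, 0.95}

    def test_snp_dosage_kept_additive(self, tiny_cohort, tiny_genotypes):
        X, _, _ = encode(tiny_cohort, tiny_genotypes, ["snpA"],
                         ["s1", "s2", "s3"])
        assert X["snpA"].tolist() == [0.0, 1.0, 2.0]

    def test_train_anchored_standardization(self, tiny_cohort):
        """A test value equal to the training mean encodes to exactly 0,
        whatever the test distribution looks like."""
        X, _, enc = encode(tiny_cohort, None, ["age"], ["s1", "s2", "s3"])
        geometric_mean = float(np.exp(np.log([45.0, 60.0, 38.0]).mean()))
        probe = tiny_cohort.data.copy()
        probe.loc["s4", "age"] = geometric_mean
        probe_cohort = CohortTable(probe, tiny_cohort.dichotomous,
                                   tiny_cohort.continuous)
        X_te, _ = encoded_rows(probe_cohort, None, enc, ["s4"])
        assert X_te.loc["s4", "age"] == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_continuous_is_error(self, tiny_cohort):
        bad = tiny_cohort.data.copy()
        bad.loc["s1", "age"] = -2.0
        cohort = CohortTable(bad, tiny_cohort.dichotomous,
                             tiny_cohort.continuous)
        with pytest.raises(ValueError, match="offset"):
            encode(cohort, None, ["age"], cohort.sample_ids)

    def test_incomplete_rows_dropped(self, tiny_cohort):
        X, y, _ = encode(tiny_cohort, None, ["hba1c"],
                         tiny_cohort.sample_ids)
        assert list(X.index) == ["s1", "s2", "s3"]  # s4 lacks hba1c

    def test_workspace_matches_reference_encoder(self, bundle):
        """The fast numpy workspace used inside forward selection is
        numerically identical to the reference encode/transform path."""
        from remission_rank.selection import FeatureWorkspace

        cohort, gm = bundle["cohort"], bundle["genotypes"]
        feats = ["hba1c", "insulin_medication", "serum_insulin",
                 gm.snp_ids[0]]
        ids = cohort.sample_ids
        train, test = ids[:100], ids[100:]
        ws = FeatureWorkspace(cohort, gm, feats, train, test)
        X_tr_w, y_tr_w, X_te_w, y_te_w = ws.encoded(feats)
        X_tr, y_tr, enc = encode(cohort, gm, feats, train)
        X_te, y_te = encoded_rows(cohort, gm, enc, test)
        np.testing.assert_allclose(X_tr_w, X_tr.to_numpy(), atol=1e-12)
        np.testing.assert_allclose(X_te_w, X_te.to_numpy(), atol=1e-12)
        np.testing.assert_array_equal(y_tr_w, y_tr.to_numpy())
        np.testing.assert_array_equal(y_te_w, y_te.to_numpy())


class TestTraining:
    def _toy(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"a": np.r_[rng.normal(-2, 0.3, n // 2),
                                     rng.normal(2, 0.3, n // 2)],
                          "b": rng.normal(0, 1, n)})
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        return X, y

    def test_separable_toy_reaches_perfect_training_auc(self):
        X, y = self._toy()
        model = train_ann(X, y, StudyConfig(), seed=1)
        assert roc_auc(predict_score(model, X), y) == 1.0

    def test_permuted_labels_give_chance_heldout_auc(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((200, 4)),
                         columns=list("abcd"))
        y = rng.permutation(np.r_[np.zeros(100), np.ones(100)])
        model = train_ann(X.iloc[:120], y[:120], StudyConfig(), seed=2)
        auc = roc_auc(predict_score(model, X.iloc[120:]), y[120:])
        assert 0.35 < auc < 0.65

    def test_same_seed_reproduces_weights(self):
        X, y = self._toy()
        m1 = train_ann(X, y, StudyConfig(), seed=7)
        m2 = train_ann(X, y, StudyConfig(), seed=7)
        np.testing.assert_array_equal(m1.w_in, m2.w_in)
        np.testing.assert_array_equal(m1.w_out, m2.w_out)

    def test_single_class_labels_rejected(self):
        X, _ = self._toy()
        with pytest.raises(ValueError, match="both classes"):
            train_ann(X, np.zeros(len(X)), StudyConfig(), seed=0)

    def test_missing_values_rejected(self):
        X, y = self._toy()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            train_ann(X, y, StudyConfig(), seed=0)

    def test_optimizer_improves_on_initial_loss(self):
        X, y = self._toy()
        cfg = StudyConfig()
        model = train_ann(X, y, cfg, seed=3)
        theta0 = np.random.default_rng(3).uniform(
            -0.5, 0.5, X.shape[1] * 3 + 7)
        theta_fit = np.concatenate([model.w_in.ravel(), model.b_hidden,
                                    model.w_out, [model.b_out]])
        Xv = X.to_numpy(float)
        l0, _ = _loss_grad_numpy(theta0, Xv, y, 1.0, X.shape[1], 3)
        l1, _ = _loss_grad_numpy(theta_fit, Xv, y, 1.0, X.shape[1], 3)
        assert l1 < l0

    def test_jit_objective_matches_numpy_reference(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((30, 5))
        y = rng.integers(0, 2, 30).astype(float)
        theta = rng.uniform(-1, 1, 5 * 3 + 7)
        l_np, g_np = _loss_grad_numpy(theta, X, y, 1.0, 5, 3)
        l_jit, g_jit = _loss_grad(theta, X, y, 1.0, 5, 3)
        assert l_jit == pytest.approx(l_np, rel=1e-12)
        np.testing.assert_allclose(g_jit, g_np, atol=1e-10)


class TestPrediction:
    def _zero_model(self, features):
        f = len(features)
        return AnnModel(features=features, w_in=np.zeros((f, 3)),
                        b_hidden=np.zeros(3), w_out=np.zeros(3), b_out=0.0,
                        weight_decay=1.0, max_iterations=1000, seed=0)

    def test_zero_weights_score_half(self):
        model = self._zero_model(["a"])
        X = pd.DataFrame({"a": [0.0, 5.0, -3.0]})
        np.testing.assert_allclose(predict_score(model, X), 0.5)

    def test_all_positive_path_is_monotone(self):
        model = AnnModel(features=["a"], w_in=np.full((1, 3), 0.8),
                         b_hidden=np.zeros(3), w_out=np.full(3, 1.2),
                         b_out=-1.0, weight_decay=1.0, max_iterations=1000,
                         seed=0)
        xs = pd.DataFrame({"a": np.linspace(-3, 3, 25)})
        scores = predict_score(model, xs)
        assert np.all(np.diff(scores) > 0)

    def test_scores_stay_in_unit_interval(self):
        rng = np.random.default_rng(0)
        model = AnnModel(features=["a", "b"],
                         w_in=rng.normal(0, 5, (2, 3)),
                         b_hidden=rng.normal(0, 5, 3),
                         w_out=rng.normal(0, 5, 3), b_out=0.0,
                         weight_decay=1.0, max_iterations=1000, seed=0)
        X = pd.DataFrame(rng.normal(0, 10, (50, 2)), columns=["a", "b"])
        s = predict_score(model, X)
        assert np.all((s >= 0) & (s <= 1))

    def test_feature_mismatch_reported(self):
        model = self._zero_model(["a", "b"])
        with pytest.raises(ValueError, match="missing feature"):
            predict_score(model, pd.DataFrame({"a": [1.0]}))


class TestImportance:
    def _model(self, w_in, w_out, features):
        w_in = np.asarray(w_in, dtype=float)
        w_out = np.asarray(w_out, dtype=float)
        return AnnModel(features=features, w_in=w_in,
                        b_hidden=np.zeros(w_in.shape[1]), w_out=w_out,
                        b_out=0.0, weight_decay=1.0, max_iterations=1000,
                        seed=0)

    def test_single_hidden_unit_product_rule(self):
        m = self._model([[2.0], [0.0]], [3.0], ["f1", "f2"])
        # raw importances (6, 0) scale to (1, 0)
        table = olden_importance([m])
        assert table.loc["f1", "importance"] == pytest.approx(1.0)
        assert table.loc["f2", "importance"] == pytest.approx(0.0)

    def test_sign_flip(self):
        m = self._model([[-2.0]], [3.0], ["f1"])
        assert olden_importance([m]).loc["f1", "importance"] == -1.0

    def test_average_over_models(self):
        m1 = self._model([[2.0], [1.0]], [3.0], ["f1", "f2"])
        m2 = self._model([[-2.0], [1.0]], [3.0], ["f1", "f2"])
        table = olden_importance([m1, m2])
        assert table.loc["f1", "importance"] == pytest.approx(0.0)
        assert table.loc["f2", "importance"] == pytest.approx(0.5)

    def test_inconsistent_feature_lists_rejected(self):
        m1 = self._model([[1.0]], [1.0], ["f1"])
        m2 = self._model([[1.0]], [1.0], ["f2"])
        with pytest.raises(ValueError, match="inconsistent"):
            olden_importance([m1, m2])

    def test_noise_feature_importance_near_zero(self):
        """A pure-noise column earns far less connection-weight
        importance than a strongly predictive one."""
        rng = np.random.default_rng(4)
        n = 300
        signal = rng.normal(0, 1, n)
        X = pd.DataFrame({"signal": signal,
                          "noise": rng.normal(0, 1, n)})
        y = (rng.random(n) < 1 / (1 + np.exp(-3 * signal))).astype(float)
        models = [train_ann(X, y, StudyConfig(), seed=s) for s in range(3)]
        table = olden_importance(models)
        assert abs(table.loc["signal", "importance"]) > 0.9
        assert abs(table.loc["noise", "importance"]) < 0.3


def test_model_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("abc"))
    y = rng.integers(0, 2, 60).astype(float)
    y[:5], y[-5:] = 0, 1
    model = train_ann(X, y, StudyConfig(), seed=9)
    model.to_text(tmp_path / "model.json")
    loaded = AnnModel.from_text(tmp_path / "model.json")
    np.testing.assert_array_equal(model.w_in, loaded.w_in)
    np.testing.assert_allclose(predict_score(model, X),
                               predict_score(loaded, X))
    assert loaded.seed == 9 and loaded.features == ["a", "b", "c"]
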