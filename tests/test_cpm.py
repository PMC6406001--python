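"""Prediction pipeline: residualization, screening, LOOCV, union model, OOS."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from flowgc import cpm
from flowgc.errors import DimensionError, ValidationError


def _behavior(scores, ages=None, sexes=None):
    k = len(scores)
    rng = np.random.default_rng(5)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(k)],
            "score": np.asarray(scores, float),
            "age": ages if ages is not None else rng.integers(22, 37, k).astype(float),
            "sex": sexes if sexes is not None else
                   np.where(rng.integers(0, 2, k) == 1, "male", "female"),
            "head_motion": np.full(k, 0.05),
        }
    )


def _planted_features(rng, k=120, e=50, n_pred=10, beta=1.0, noise=1.0):
    """Feature matrix with the first n_pred columns driving the score."""
    latent = rng.normal(size=k)
    F = rng.normal(size=(k, e)) * 0.3
    F[:, :n_pred] += latent[:, None]
    scores = 100 + beta * latent + rng.normal(scale=noise, size=k)
    return F, _behavior(scores)


class TestResidualize:
    def test_uncorrelated_covariates_residuals_centered(self, rng):
        scores = rng.normal(size=200) + 50
        b = _behavior(scores)
        resid, _ = cpm.residualize_scores(b)
        np.testing.assert_allclose(resid, scores - scores.mean(), atol=1.0)
        assert abs(resid.mean()) < 1e-9

    def test_perfect_covariate_fit_zero_residuals(self):
        ages = np.linspace(22, 36, 40)
        b = _behavior(2 * ages, ages=ages, sexes=["male"] * 40)
        with pytest.warns(UserWarning, match="sex"):
            resid, _ = cpm.residualize_scores(b)
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    def test_frozen_model_reused_on_new_subjects(self, rng):
        b_train = _behavior(rng.normal(size=50) + 10)
        _, model = cpm.residualize_scores(b_train)
        b_test = _behavior(rng.normal(size=20) + 10)
        adj = model.adjust(b_test["score"].to_numpy(), b_test)
        X = np.column_stack([np.ones(20), b_test["age"],
                             cpm.encode_sex(b_test["sex"])])
        np.testing.assert_allclose(adj, b_test["score"].to_numpy() - X @ model.coef)


class TestStep2:
    def test_perfect_edge_selected_positive(self, rng):
        scores = rng.normal(size=40)
        F = rng.normal(size=(40, 5))
        F[:, 2] = scores
        pos, neg = cpm.step2_select(F, scores, p_thresh=0.005)
        assert 2 in pos and len(neg) == 0

    def test_null_selection_rate_matches_threshold(self, rng):
        k, e = 60, 4000
        F = rng.normal(size=(k, e))
        scores = rng.normal(size=k)
        pos, neg = cpm.step2_select(F, scores, p_thresh=0.01)
        frac = (len(pos) + len(neg)) / e
        assert 0.003 < frac < 0.025

    def test_sign_split_partitions_selection(self, rng):
        F, b = _planted_features(rng)
        resid, _ = cpm.residualize_scores(b)
        pos, neg = cpm.step2_select(F, resid, p_thresh=0.05)
        assert len(np.intersect1d(pos, neg)) == 0

    def test_zero_variance_edge_never_selected(self, rng):
        F = rng.normal(size=(30, 3))
        F[:, 1] = 7.0
        pos, neg = cpm.step2_select(F, rng.normal(size=30), p_thresh=0.5)
        assert 1 not in pos and 1 not in neg


class TestLoocv:
    def test_noiseless_signal_near_perfect(self, rng):
        k = 30
        F = rng.normal(size=(k, 8))
        b = _behavior(100 + 2.5 * F[:, 3], ages=np.full(k, 30.0),
                      sexes=["female"] * k)
        out = cpm.loocv(F, b, p_step2=0.005)
        assert out["positive"].r > 0.99

    def test_no_leakage_sentinel(self, rng):
        F, b = _planted_features(rng, k=40)
        out = cpm.loocv(F, b)
        b2 = b.copy()
        b2.loc[7, "score"] += 1000.0      # corrupt only the holdout's own score
        out2 = cpm.loocv(F, b2)
        assert out2["positive"].predicted[7] == out["positive"].predicted[7]

    def test_empty_folds_predict_training_mean(self, rng):
        F = rng.normal(size=(25, 6))
        b = _behavior(rng.normal(size=25))
        out = cpm.loocv(F, b, p_step2=1e-12)
        assert out["n_empty"]["positive"] == 25
        np.testing.assert_allclose(out["positive"].predicted, 0.0, atol=1e-9)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValidationError):
            cpm.loocv(rng.normal(size=(10, 4)), _behavior(rng.normal(size=10)))


class TestUnion:
    def test_identical_folds_idempotent(self, rng):
        F, b = _planted_features(rng, k=60)
        sets = [{"positive": np.array([1, 2]), "negative": np.array([5])}] * 10
        model = cpm.union_weight_map(sets, F, b)
        np.testing.assert_array_equal(model.positive_edges, [1, 2])
        np.testing.assert_array_equal(model.negative_edges, [5])

    def test_union_contains_every_fold(self, rng):
        F, b = _planted_features(rng, k=60)
        out = cpm.loocv(F, b, p_step2=0.01)
        model = cpm.union_weight_map(out["fold_sets"], F, b, p_step2=0.01)
        for fs in out["fold_sets"]:
            assert set(fs["positive"]) <= set(model.positive_edges)

    def test_recovers_planted_predictive_edges(self, rng):
        F, b = _planted_features(rng, k=120, n_pred=10)
        out = cpm.loocv(F, b)
        model = cpm.union_weight_map(out["fold_sets"], F, b)
        assert len(set(range(10)) & set(model.positive_edges)) >= 8

    def test_conflicting_sign_resolved_by_full_sample(self, rng):
        F, b = _planted_features(rng, k=60)
        sets = [{"positive": np.array([0]), "negative": np.array([], dtype=int)},
                {"positive": np.array([], dtype=int), "negative": np.array([0])}]
        model = cpm.union_weight_map(sets, F, b)
        assert (0 in model.positive_edges) != (0 in model.negative_edges)


class TestOos:
    def test_training_set_reproduces_fitted_values(self, rng):
        F, b = _planted_features(rng, k=60)
        out = cpm.loocv(F, b)
        model = cpm.union_weight_map(out["fold_sets"], F, b)
        res = cpm.predict_oos(model, F, b)
        s = model.summed_feature(F, "positive")
        b0, b1 = model.beta_pos
        np.testing.assert_allclose(res.predicted, b0 + b1 * s)

    def test_shuffled_features_destroy_signal(self, rng):
        F, b = _planted_features(rng, k=100)
        half = 60
        out = cpm.loocv(F[:half], b.iloc[:half].reset_index(drop=True))
        model = cpm.union_weight_map(out["fold_sets"], F[:half],
                                     b.iloc[:half].reset_index(drop=True))
        bt = b.iloc[half:].reset_index(drop=True)
        good = cpm.predict_oos(model, F[half:], bt)
        shuf = cpm.predict_oos(model, rng.permutation(F[half:]), bt)
        assert good.r > 0.5
        assert abs(shuf.r) < good.r

    def test_missing_edges_dimension_error(self, rng):
        F, b = _planted_features(rng, k=60)
        out = cpm.loocv(F, b)
        model = cpm.union_weight_map(out["fold_sets"], F, b)
        with pytest.raises(DimensionError):
            model.predict(F[:, :-1])


class TestPermutation:
    def test_extreme_rank_gives_add_one_p(self):
        p = cpm.permutation_test(lambda s: -1.0, np.arange(30.0), observed_r=0.9,
                                 n_perm=100, seed=1)
        assert p == pytest.approx(1 / 101)

    def test_seed_determinism(self, rng):
        F, b = _planted_features(rng, k=60)
        scores = b["score"].to_numpy()

        def ev(perm):
            bb = b.copy()
            bb["score"] = perm
            out = cpm.loocv(F, bb)
            return out["positive"].r

        p1 = cpm.permutation_test(ev, scores, 0.3, n_perm=100, seed=11)
        p2 = cpm.permutation_test(ev, scores, 0.3, n_perm=100, seed=11)
        assert p1 == p2

    def test_minimum_permutations_enforced(self):
        with pytest.raises(ValidationError):
            cpm.permutation_test(lambda s: 0.0, np.arange(10.0), 0.0, n_perm=10)


class TestEstimator:
    def test_sklearn_contract(self, rng):
        F, b = _planted_features(rng, k=60)
        est = cpm.CpmRegressor(p_step2=0.01)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()
        est.fit(F, behavior=b)
        assert est.n_features_in_ == F.shape[1]
        pred = est.predict(F)
        assert pred.shape == (60,)

    def test_fit_with_plain_y(self, rng):
        F, b = _planted_features(rng, k=60)
        est = cpm.CpmRegressor().fit(F, y=b["score"].to_numpy())
        assert hasattr(est, "model_")

    def test_evaluate_matches_predict_oos(self, rng):
        F, b = _planted_features(rng, k=60)
        est = cpm.CpmRegressor().fit(F, behavior=b)
        res = est.evaluate(F, b)
        np.testing.assert_allclose(res.predicted, est.predict(F))
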