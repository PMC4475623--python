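"""The nine classification functions: grids, contracts, oracles."""

import numpy as np
import pytest

from exprbench.classifiers import (
    CLASSIFIER_NAMES,
    ClassifierSpec,
    default_grids,
    fit,
    predict_from_study,
    reduced_grids,
)
from exprbench.study import ExpressionStudy

from _oracles import max_margin_2d_bruteforce

#: one cheap representative grid point per classifier, for contract tests
CHEAP_PARAMS = {
    "LDA": {},
    "DLDA": {},
    "SCDA": {"lam": 0.5},
    "RF": {"n_trees": 30, "m_mult": 1, "min_node": 1},
    "TBB": {"n_rounds": 20},
    "RIDGE": {"lam": 1},
    "LASSO": {"lam": 0.3},
    "SVM": {"C": 1},
    "KNN": {"k": 3},
}


def _toy(rng, n_per_class=15, p=6, shift=1.5):
    X = rng.standard_normal((2 * n_per_class, p))
    X[:n_per_class] += shift
    y = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    return X, y


class TestGrids:
    def test_tuning_grids_have_the_reference_values(self):
        g = default_grids()
        assert g["SCDA"].param_grid["lam"] == (0.1, 0.25, 0.5, 1, 2, 5)
        assert g["RF"].param_grid["n_trees"] == (500,)
        assert g["RF"].param_grid["m_mult"] == (0.1, 0.25, 0.5, 1, 2)
        assert g["RF"].param_grid["min_node"] == (1, 2, 3)
        assert g["TBB"].param_grid["n_rounds"] == (50, 100, 200, 500, 1000)
        assert g["RIDGE"].param_grid["lam"] == (0.0625, 0.125, 0.25, 0.5, 1, 2, 4, 8, 16)
        assert g["LASSO"].param_grid["lam"] == tuple(
            round(0.1 * i, 1) for i in range(1, 10)
        )
        assert g["SVM"].param_grid["C"] == (0.1, 1, 5, 10, 50, 100, 500)
        assert g["KNN"].param_grid["k"] == tuple(range(1, 11))

    def test_top_p_grids(self):
        g = default_grids()
        for name in CLASSIFIER_NAMES:
            if name in ("LDA", "DLDA"):
                assert g[name].top_p_grid == (2, 3, 4, 5)
            else:
                assert g[name].top_p_grid == (5, 10, 15, 20, 25, 50, 55)

    def test_reduced_grids_cover_all_methods(self):
        assert set(reduced_grids()) == set(CLASSIFIER_NAMES)


class TestContracts:
    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_label_swap_equivariance(self, name, rng):
        X, y = _toy(rng)
        spec = ClassifierSpec(name, {}, (6,))
        m1 = fit(spec, X, y, CHEAP_PARAMS[name], seed=3)
        y_sw = np.where(y == "A", "B", "A")
        m2 = fit(spec, X, y_sw, CHEAP_PARAMS[name], seed=3)
        Xt = rng.standard_normal((10, 6)) + 0.75
        p1 = m1.predict(Xt)
        p2 = m2.predict(Xt)
        assert (p1 != p2).sum() == 0 or (np.where(p1 == "A", "B", "A") == p2).all()

    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_one_class_input_rejected(self, name, rng):
        X = rng.standard_normal((10, 4))
        y = np.array(["A"] * 10)
        with pytest.raises(ValueError, match="two classes"):
            fit(ClassifierSpec(name, {}, (4,)), X, y, CHEAP_PARAMS[name])

    @pytest.mark.parametrize("name", ["DLDA", "SCDA", "KNN"])
    def test_location_invariance(self, name, rng):
        """Adding a constant to one probeset (learning and test) leaves
        predictions unchanged for centroid/distance-based rules."""
        X, y = _toy(rng)
        Xt = rng.standard_normal((12, 6)) + 0.75
        spec = ClassifierSpec(name, {}, (6,))
        base = fit(spec, X, y, CHEAP_PARAMS[name], seed=0).predict(Xt)
        X2, Xt2 = X.copy(), Xt.copy()
        X2[:, 2] += 50.0
        Xt2[:, 2] += 50.0
        shifted = fit(spec, X2, y, CHEAP_PARAMS[name], seed=0).predict(Xt2)
        assert (base == shifted).all()

    @pytest.mark.parametrize("name", ["RF", "TBB"])
    def test_ensemble_reproducible_given_seed(self, name, rng):
        X, y = _toy(rng, shift=0.5)
        Xt = rng.standard_normal((20, 6))
        spec = ClassifierSpec(name, {}, (6,))
        a = fit(spec, X, y, CHEAP_PARAMS[name], seed=11).predict(Xt)
        b = fit(spec, X, y, CHEAP_PARAMS[name], seed=11).predict(Xt)
        assert (a == b).all()

    def test_predict_from_study_names_missing_probesets(self, rng):
        X, y = _toy(rng, p=3)
        model = fit(
            ClassifierSpec("KNN", {}, (3,)), X, y, {"k": 1},
            probeset_ids=["g1", "g2", "g9"],
        )
        study = ExpressionStudy(
            "s", rng.standard_normal((2, 4)) + 8,
            np.array(["A", "A", "B", "B"]), ["g1", "g2"], list("wxyz"),
        )
        with pytest.raises(KeyError, match="g9"):
            predict_from_study(model, study)


class TestMethodSpecifics:
    def test_knn_k1_resubstitution_is_perfect(self, rng):
        X, y = _toy(rng, shift=0.2)
        m = fit(ClassifierSpec("KNN", {}, (6,)), X, y, {"k": 1})
        assert (m.predict(X) == y).all()

    def test_knn_vote_tie_goes_to_nearest_neighbour(self):
        # two A's at distance 1 and 2; two B's at distance 1.5 and 1.6 -> k=4
        # vote 2-2, nearest is A
        X = np.array([[1.0], [2.0], [-1.5], [-1.6]])
        y = np.array(["A", "A", "B", "B"])
        m = fit(ClassifierSpec("KNN", {}, (1,)), X, y, {"k": 4})
        assert m.predict(np.array([[0.0]]))[0] == "A"

    def test_scda_full_shrinkage_predicts_majority(self, rng):
        X = rng.standard_normal((30, 8))
        y = np.array(["A"] * 20 + ["B"] * 10)
        m = fit(ClassifierSpec("SCDA", {}, (8,)), X, y, {"lam": 1e6})
        assert (m.predict(rng.standard_normal((15, 8))) == "A").all()

    def test_scda_balanced_full_shrinkage_tie_is_first_label(self, rng):
        X = rng.standard_normal((20, 5))
        y = np.array(["A"] * 10 + ["B"] * 10)
        m = fit(ClassifierSpec("SCDA", {}, (5,)), X, y, {"lam": 1e6})
        assert (m.predict(rng.standard_normal((7, 5))) == "A").all()

    def test_ridge_large_lambda_approaches_majority_class(self, rng):
        X, y = _toy(rng, n_per_class=10)
        X = np.vstack([X, rng.standard_normal((8, 6))])
        y = np.concatenate([y, ["A"] * 8])  # majority A
        m = fit(ClassifierSpec("RIDGE", {}, (6,)), X, y, {"lam": 1e6})
        assert (m.predict(rng.standard_normal((20, 6))) == "A").all()

    def test_lda_recovers_population_discriminant(self):
        rng = np.random.default_rng(42)
        mu1, mu2 = np.array([1.0, 0.5]), np.array([-0.5, 0.0])
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        chol = np.linalg.cholesky(cov)
        n = 200
        X = np.vstack(
            [rng.standard_normal((n, 2)) @ chol.T + mu1,
             rng.standard_normal((n, 2)) @ chol.T + mu2]
        )
        y = np.array(["A"] * n + ["B"] * n)
        m = fit(ClassifierSpec("LDA", {}, (2,)), X, y, {})
        w_hat = m._predictor.icov_mu[0] - m._predictor.icov_mu[1]
        w_pop = np.linalg.solve(cov, mu1 - mu2)
        w_hat /= np.linalg.norm(w_hat)
        w_pop /= np.linalg.norm(w_pop)
        assert np.linalg.norm(w_hat - w_pop) < 0.1

    def test_lda_rejects_p_not_less_than_n(self, rng):
        X, y = _toy(rng, n_per_class=3, p=6)
        with pytest.raises(ValueError, match="smaller top-p"):
            fit(ClassifierSpec("LDA", {}, (6,)), X, y, {})

    @pytest.mark.parametrize("C", [0.1, 1, 5, 10, 50, 100, 500])
    def test_svm_agrees_with_bruteforce_margin_maximizer(self, C):
        """On a separable 8-point 2-D toy, held-out predictions fall on the
        same side as the exhaustively found maximum-margin line."""
        X = np.array(
            [[1.0, 1.2], [2.0, 0.8], [1.5, 2.0], [2.5, 1.5],
             [-1.0, -0.8], [-2.0, -1.5], [-1.2, -2.0], [-0.5, -1.8]]
        )
        y = np.array(["A"] * 4 + ["B"] * 4)
        m = fit(ClassifierSpec("SVM", {}, (2,)), X, y, {"C": C})
        # the wrapper standardizes; the oracle works on the same scale
        mean, sd = X.mean(0), X.std(0, ddof=1)
        Xs = (X - mean) / sd
        w, b, margin = max_margin_2d_bruteforce(Xs, (y == "B").astype(int))
        assert margin > 0
        rng = np.random.default_rng(0)
        held = rng.uniform(-3, 3, (40, 2))
        helds = (held - mean) / sd
        side = np.where(helds @ w + b > 0, "B", "A")
        clear = np.abs(helds @ w + b) > 0.25 * margin
        pred = m.predict(held)
        assert (pred[clear] == side[clear]).all()

    def test_rf_feature_subsampling_parameter_rounds_with_floor_one(self, rng):
        X, y = _toy(rng, p=5)
        m = fit(
            ClassifierSpec("RF", {}, (5,)), X, y,
            {"n_trees": 10, "m_mult": 0.1, "min_node": 1}, seed=2,
        )
        assert m._predictor.est.max_features == 1  # 0.1*sqrt(5) rounds to 0 -> floor 1
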