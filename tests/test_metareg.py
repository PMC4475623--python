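"""Crossed random-intercept meta-regression: fitter and model selection."""

import numpy as np
import pandas as pd
import pytest

from exprbench.metareg import (
    build_table,
    explained_variation,
    fit_glmm,
    forward_select,
    jackknife,
    univariable_scan,
)
from exprbench.simulate import simulate_grouped_binomial

from _oracles import glmm_loglik_quadrature


def _table(seed=1, S=25, M=6, trials=80, betas=(0.5, -1.0, 0.8), ss=0.4, sm=0.25):
    t = simulate_grouped_binomial(S, M, betas, ss, sm, trials, seed=seed)
    return t.rename(columns={"x1": "class_imbalance", "x2": "f"})


class TestBuildTable:
    def _bench_frame(self):
        rows = []
        for s in range(4):
            for m, clf in enumerate(["KNN", "DLDA", "SVM"]):
                for b in range(2):
                    rows.append(
                        dict(
                            study_id=f"S{s}", classifier=clf, split=b,
                            test_correct=5 + m, test_total=8,
                            learn_correct=15, learn_total=16, error="",
                        )
                    )
        return pd.DataFrame(rows)

    def _factors_frame(self):
        return pd.DataFrame(
            {
                "study_id": [f"S{s}" for s in range(4)],
                "class_imbalance": [0.5, 0.6, 0.7, 0.55],
                "log2_pDEG": [0.0, 2.0, 5.0, 7.0],
            }
        )

    def test_one_row_per_study_method_with_summed_counts(self):
        table = build_table(self._bench_frame(), self._factors_frame())
        assert len(table) == 12
        knn = table[(table.study_id == "S0") & (table.method_id == "KNN")]
        assert int(knn["successes"].iloc[0]) == 10  # 5 correct x 2 splits
        assert int(knn["trials"].iloc[0]) == 16

    def test_missing_factors_row_is_an_error(self):
        with pytest.raises(KeyError, match="S3"):
            build_table(self._bench_frame(), self._factors_frame().iloc[:3])

    def test_successes_exceeding_trials_rejected(self):
        table = build_table(self._bench_frame(), self._factors_frame())
        table.loc[0, "successes"] = table.loc[0, "trials"] + 1
        with pytest.raises(ValueError, match="successes"):
            fit_glmm(table, [])

    def test_csv_roundtrip_identity(self, tmp_path):
        table = build_table(self._bench_frame(), self._factors_frame())
        path = tmp_path / "t.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, table)


class TestFitGlmm:
    def test_zero_variance_limit_matches_plain_logistic(self):
        import statsmodels.api as sm

        t = _table(seed=3, S=30, M=5, trials=150, ss=0.0, sm=0.0)
        f = fit_glmm(t, ["f"], standardize=False)
        assert f.sigma_s_sq < 0.01 and f.sigma_m_sq < 0.01
        X = np.column_stack(
            [np.ones(len(t)), t["class_imbalance"], t["f"]]
        )
        y = np.column_stack([t["successes"], t["trials"] - t["successes"]])
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(f.beta, ref.params, atol=3 * ref.bse.max())

    def test_laplace_loglik_matches_quadrature_on_tiny_instance(self):
        """Small-instance oracle: fine Gauss-Hermite integration of the
        marginal likelihood agrees with the Laplace value within 1%."""
        from exprbench.metareg import _design, _LaplaceEngine

        for seed in (1, 2):
            t = _table(seed=seed, S=3, M=2, trials=15, ss=0.6, sm=0.4)
            X, _, _ = _design(t, ["f"], standardize=False)
            y = t["successes"].to_numpy(float)
            n = t["trials"].to_numpy(float)
            studies = sorted(t["study_id"].unique())
            methods = sorted(t["method_id"].unique())
            s_idx = t["study_id"].map({s: i for i, s in enumerate(studies)}).to_numpy()
            m_idx = t["method_id"].map({m: i for i, m in enumerate(methods)}).to_numpy()
            engine = _LaplaceEngine(X, y, n, s_idx, m_idx, 3, 2)
            beta = np.array([0.4, -0.8, 0.6])
            ll_lap, _ = engine.loglik(beta, 0.5, 0.3)
            ll_quad = glmm_loglik_quadrature(
                beta, 0.5, 0.3, X, y, n, s_idx, m_idx, 3, 2, nodes=40
            )
            assert abs(ll_lap - ll_quad) / abs(ll_quad) < 0.01

    def test_doubling_counts_keeps_beta_and_shrinks_se(self):
        # in the no-random-effect limit the binomial information doubles,
        # so fixed-effect SEs shrink by ~sqrt(2); with random effects the
        # cluster-level variance would dominate and mask the scaling
        t = _table(seed=5, ss=0.0, sm=0.0)
        f1 = fit_glmm(t, ["f"], standardize=False)
        t2 = t.copy()
        t2["successes"] *= 2
        t2["trials"] *= 2
        f2 = fit_glmm(t2, ["f"], standardize=False)
        assert np.allclose(f1.beta, f2.beta, atol=0.02)
        assert (f2.se < f1.se).all()

    def test_row_order_invariance(self):
        t = _table(seed=6)
        f1 = fit_glmm(t, ["f"])
        shuffled = t.sample(frac=1.0, random_state=9).reset_index(drop=True)
        f2 = fit_glmm(shuffled, ["f"])
        assert np.allclose(f1.beta, f2.beta, atol=1e-5)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)

    def test_standardization_backtransform_consistent(self):
        t = _table(seed=7)
        raw = fit_glmm(t, ["f"], standardize=False)
        std = fit_glmm(t, ["f"], standardize=True)
        assert np.allclose(raw.beta_raw, std.beta_raw, atol=0.02)

    def test_constant_covariate_rejected(self):
        t = _table(seed=8)
        t["flat"] = 1.7
        with pytest.raises(ValueError, match="constant"):
            fit_glmm(t, ["flat"])


class TestExplainedVariation:
    def test_null_against_itself_is_exactly_zero(self):
        t = _table(seed=9)
        null = fit_glmm(t, [])
        assert explained_variation(null, null).var_l == 0.0

    def test_forced_arithmetic(self):
        t = _table(seed=9)
        null = fit_glmm(t, [])
        fac = fit_glmm(t, ["f"])
        null.sigma_s_sq, null.sigma_m_sq = 0.75, 0.25
        fac.sigma_s_sq, fac.sigma_m_sq = 0.2, 0.05
        assert explained_variation(null, fac).var_l == pytest.approx(0.75)

    def test_zero_null_variance_is_an_error(self):
        t = _table(seed=9)
        null = fit_glmm(t, [])
        null.sigma_s_sq = null.sigma_m_sq = 0.0
        with pytest.raises(ValueError, match="zero combined variance"):
            explained_variation(null, null)

    def test_covariate_driving_intercepts_recovers_variation(self):
        """If study intercepts are an exact function of a covariate, adding
        it should absorb most of the study-level variance."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        t = simulate_grouped_binomial(
            50, 4, [0.2, -0.5, 1.0], 0.0, 0.2, 200, seed=4,
            covariates=np.column_stack([rng.standard_normal(50), x]),
        )
        t = t.rename(columns={"x1": "class_imbalance", "x2": "f"})
        null = fit_glmm(t, [])
        fac = fit_glmm(t, ["f"])
        assert explained_variation(null, fac).var_l >= 0.7


class TestSelection:
    def test_scan_returns_one_row_per_candidate_sorted(self):
        t = _table(seed=10)
        t["noise"] = np.repeat(
            np.random.default_rng(0).standard_normal(25), 6
        )
        scan = univariable_scan(t, ["f", "noise"])
        assert list(scan["factor"]) in (["f", "noise"], ["noise", "f"])
        assert len(scan) == 2
        assert scan.iloc[0]["var_l"] >= scan.iloc[1]["var_l"]
        assert scan.iloc[0]["factor"] == "f"

    def test_forward_selection_keeps_generating_factor_and_aic_decreases(self):
        t = _table(seed=11, S=40, trials=150)
        t["noise"] = np.repeat(
            np.random.default_rng(1).standard_normal(40), 6
        )
        trace, final = forward_select(t, ["f", "noise"])
        assert "f" in trace.selected
        aics = [trace.null_aic] + [s["new_aic"] for s in trace.steps if s["chosen"]]
        assert all(a2 < a1 for a1, a2 in zip(aics, aics[1:]))
        assert final.aic == trace.final_aic


class TestJackknife:
    def test_one_run_per_study_and_agreement_bounds(self):
        t = _table(seed=12, S=10, M=4, trials=120)
        rep = jackknife(t, ["f"])
        assert len(rep.per_study) == 10
        assert 0.0 <= rep.agreement <= 1.0
        assert {c for c in rep.per_study.columns} >= {"left_out", "selected", "agrees"}

    def test_duplicated_study_leaves_selection_unchanged(self):
        t = _table(seed=13, S=12, M=4, trials=150, betas=(0.5, -1.0, 1.2))
        dup = t[t["study_id"] == "S000"].copy()
        dup["study_id"] = "S_dup"
        t2 = pd.concat([t, dup], ignore_index=True)
        full_trace, _ = forward_select(t2, ["f"])
        sub = t2[t2["study_id"] != "S_dup"]
        trace, _ = forward_select(sub, ["f"])
        assert set(trace.selected) == set(full_trace.selected)

    def test_too_few_studies_rejected(self):
        t = _table(seed=14, S=2, M=4)
        with pytest.raises(ValueError, match=">= 3 studies"):
            jackknife(t, ["f"])
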