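"""Canned experiments over the pipeline: the analyses the package exists for.

Each function runs one self-contained study-level experiment from a seed
and returns plain dict/DataFrame summaries, so the analysis drivers, the
test suite and the acceptance script all execute exactly the same
computations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .benchmark import SplitPlan, benchmark_to_frame, run_suite_benchmark
from .classifiers import ClassifierSpec, fit, pointwise_grids
from .factors import compute_factors, factors_table
from .metareg import (
    build_table,
    explained_variation,
    fit_glmm,
    forward_select,
    univariable_scan,
)
from .preprocess import filter_probesets
from .simulate import (
    ScenarioConfig,
    factorial_suite_configs,
    simulate_grouped_binomial,
    simulate_scenario,
    simulate_suite,
)

__all__ = [
    "scenario_accuracy_curve",
    "run_recovery_suite",
    "glmm_recovery_study",
    "forward_selection_null_study",
]


def scenario_accuracy_curve(
    cc_sign: int,
    rhos=(0.0, 0.3, 0.6, 0.9),
    n_rep: int = 200,
    delta: float = 1.0,
    n_per_class: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out LDA accuracy of two-gene scenarios across correlation levels.

    Gene 1 is up-, gene 2 down-regulated (opposite fold-change signs); the
    within-class correlation is ``cc_sign * rho``.  Each replicate trains
    LDA on two thirds of each class and tests on the rest.  Returns one row
    per (rho, replicate).
    """
    spec = ClassifierSpec("LDA", {}, (2,))
    n_train = int(round(2 * n_per_class / 3))
    rows = []
    for rho in rhos:
        for rep in range(n_rep):
            s = seed + 7919 * rep + int(rho * 1e4)
            st = simulate_scenario(
                ScenarioConfig(1, -1, cc_sign, rho, delta, n_per_class, s)
            )
            X = st.matrix.T
            y = st.labels
            rng = np.random.default_rng(s + 1)
            tr = np.concatenate(
                [rng.permutation(np.flatnonzero(y == c))[:n_train] for c in ("A", "B")]
            )
            te = np.setdiff1d(np.arange(2 * n_per_class), tr)
            model = fit(spec, X[tr], y[tr], {})
            rows.append(
                {
                    "cc_sign": cc_sign,
                    "rho_abs": rho,
                    "rep": rep,
                    "accuracy": float((model.predict(X[te]) == y[te]).mean()),
                }
            )
    return pd.DataFrame(rows)


def run_recovery_suite(
    suite_seed: int,
    B: int = 20,
    candidates=None,
    grids: dict | None = None,
) -> dict:
    """One full factor-recovery run on the factorial suite.

    Simulates the 25-study factorial suite, filters, benchmarks all nine
    classifiers, extracts factors, and runs the univariable scan plus AIC
    forward selection.  Returns the selected set, coefficients on the raw
    scale, the top-ranked univariable factor, and the tables.
    """
    configs = factorial_suite_configs(suite_seed=suite_seed)
    studies = [
        filter_probesets(s)[0] for s in simulate_suite(configs, suite_seed=suite_seed)
    ]
    facs = factors_table([compute_factors(s) for s in studies])
    specs = list((grids or pointwise_grids()).values())
    bench = benchmark_to_frame(
        run_suite_benchmark(studies, specs, SplitPlan(B=B, seed=suite_seed))
    )
    table = build_table(bench, facs)
    null_fit = fit_glmm(table, [])
    scan = univariable_scan(table, candidates, null_fit=null_fit)
    trace, final_fit = forward_select(table, candidates)
    coefs = dict(zip(final_fit.coef_names, final_fit.beta_raw))
    ev = (
        explained_variation(null_fit, final_fit).var_l if trace.selected else 0.0
    )
    return {
        "selected": trace.selected,
        "coefficients": coefs,
        "scan": scan,
        "first_factor": scan.iloc[0]["factor"],
        "explained_variation": ev,
        "table": table,
        "factors": facs,
        "trace": trace,
        "null_fit": null_fit,
        "final_fit": final_fit,
    }


def glmm_recovery_study(
    n_rep: int = 100,
    n_studies: int = 40,
    n_methods: int = 9,
    trials: int = 100,
    betas=(0.5, -1.0, 0.8),
    sigma_s: float = 0.5,
    sigma_m: float = 0.3,
    seed: int = 0,
) -> dict:
    """Parameter recovery of the crossed random-intercept fitter.

    Repeatedly simulates grouped-binomial tables from known parameters and
    refits; reports the mean estimates, the Wald 95% CI coverage of the
    covariate effect, and mean variance components.
    """
    betas = np.asarray(betas, float)
    est_b, est_v, covered = [], [], []
    for r in range(n_rep):
        t = simulate_grouped_binomial(
            n_studies, n_methods, betas, sigma_s, sigma_m, trials,
            seed=seed + 1000 + r,
        )
        t = t.rename(columns={"x1": "class_imbalance", "x2": "factor"})
        f = fit_glmm(t, ["factor"], standardize=False)
        est_b.append(f.beta)
        est_v.append([f.sigma_s_sq, f.sigma_m_sq])
        lo, hi = f.wald_ci()[2]
        covered.append(lo <= betas[2] <= hi)
    est_b = np.array(est_b)
    est_v = np.array(est_v)
    return {
        "mean_beta": est_b.mean(axis=0),
        "mean_sigma_s_sq": float(est_v[:, 0].mean()),
        "mean_sigma_m_sq": float(est_v[:, 1].mean()),
        "coverage_beta2": float(np.mean(covered)),
        "true_betas": betas,
        "true_sigma_s_sq": sigma_s**2,
        "true_sigma_m_sq": sigma_m**2,
        "n_rep": n_rep,
    }


def forward_selection_null_study(
    n_rep: int = 50,
    n_studies: int = 50,
    n_methods: int = 9,
    trials: int = 50,
    n_noise: int = 3,
    seed: int = 0,
) -> dict:
    """How often forward selection picks anything when nothing is real.

    Tables are drawn with accuracy depending only on the class-imbalance
    covariate and random intercepts; the candidate factors are pure noise.
    """
    empty = 0
    sizes = []
    for r in range(n_rep):
        rng = np.random.default_rng(seed + 31 * r)
        cov = rng.standard_normal((n_studies, 1 + n_noise))
        t = simulate_grouped_binomial(
            n_studies, n_methods, [0.5, -1.0] + [0.0] * n_noise, 0.5, 0.3,
            trials, seed=seed + 7000 + r, covariates=cov,
        )
        t = t.rename(
            columns={"x1": "class_imbalance", **{f"x{j+2}": f"noise{j}" for j in range(n_noise)}}
        )
        trace, _ = forward_select(t, [f"noise{j}" for j in range(n_noise)])
        empty += not trace.selected
        sizes.append(len(trace.selected))
    return {
        "fraction_empty": empty / n_rep,
        "mean_selected": float(np.mean(sizes)),
        "n_rep": n_rep,
    }
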