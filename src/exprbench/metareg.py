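"""Crossed random-intercept logistic meta-regression of classifier accuracy.

Each (study S, method M) cell of a benchmark contributes a grouped binomial
outcome: the number of correctly classified test samples out of the number
classified.  The model for the probability pi that a sample is correctly
classified is

    logit(pi_SM) = (b0 + u_S + v_M) + b1 * class_imbalance_S + b.x_S,

with independent random intercepts u_S ~ N(0, sigma_S^2) for study and
v_M ~ N(0, sigma_M^2) for classification method.  Class imbalance is always
included, because raw accuracy is biased toward the majority-class rate.

Estimation is maximum likelihood with a Laplace approximation: for each
candidate (beta, sigma) the joint mode of all S + M random effects is found
by damped Newton iterations, and

    loglik = binom_loglik(mode) - u'D^-1 u / 2 - log det(I + D Z'WZ) / 2,

which is exact in the limit of either large cell counts or zero variances.
The outer optimization runs L-BFGS-B over (beta, log sigma_S, log sigma_M)
with restarts from perturbed starting points on non-convergence.

On top of the fitter sit the quantities used to compare study factors:
explained variation (the proportional reduction in the combined random
intercept variance sigma_S^2 + sigma_M^2 relative to the imbalance-only
null model), AIC forward selection, and a leave-one-study-out jackknife of
the selected factor set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "GLMMFit",
    "ExplainedVariation",
    "SelectionTrace",
    "JackknifeReport",
    "build_table",
    "fit_glmm",
    "explained_variation",
    "univariable_scan",
    "forward_select",
    "jackknife",
    "CONTINUOUS_FACTORS",
    "CATEGORICAL_FACTORS",
    "DEFAULT_CANDIDATES",
]

CONTINUOUS_FACTORS = ["log2_pDEG", "fc", "withincor", "sample_size"]
CATEGORICAL_FACTORS = ["medical_question", "cell_type"]
DEFAULT_CANDIDATES = CONTINUOUS_FACTORS + CATEGORICAL_FACTORS


# ----------------------------------------------------------------------
# table construction
# ----------------------------------------------------------------------


def build_table(benchmark: pd.DataFrame, factors: pd.DataFrame) -> pd.DataFrame:
    """Join aggregated benchmark counts with per-study factors.

    ``benchmark`` is the tidy per-split frame (study_id, classifier, split,
    test_correct, test_total, ...); counts are summed over splits so each
    (study, method) pair yields one grouped-binomial row.  ``factors`` has
    one row per study in the canonical factor-column layout.
    """
    ok = benchmark[benchmark.get("error", "").eq("")] if "error" in benchmark else benchmark
    agg = (
        ok.groupby(["study_id", "classifier"], as_index=False)
        .agg(successes=("test_correct", "sum"), trials=("test_total", "sum"))
        .rename(columns={"classifier": "method_id"})
    )
    missing = set(agg["study_id"]) - set(factors["study_id"])
    if missing:
        raise KeyError(f"no factors row for studies: {sorted(missing)}")
    table = agg.merge(factors, on="study_id", how="left")
    _validate_table(table)
    return table


def _validate_table(table: pd.DataFrame) -> None:
    req = {"study_id", "method_id", "successes", "trials"}
    if not req.issubset(table.columns):
        raise ValueError(f"table lacks columns {sorted(req - set(table.columns))}")
    if (table["successes"] < 0).any() or (table["successes"] > table["trials"]).any():
        raise ValueError("successes must lie in [0, trials] for every row")
    if table.duplicated(["study_id", "method_id"]).any():
        dup = table[table.duplicated(["study_id", "method_id"])]
        raise ValueError(
            f"duplicate (study, method) rows: {dup[['study_id', 'method_id']].values.tolist()}"
        )


def _design(table: pd.DataFrame, factor_names: list[str], standardize: bool):
    """Fixed-effect design matrix: intercept, class imbalance, then factors.

    Continuous covariates are optionally standardized (mean 0, SD 1 across
    table rows); two-level categorical factors are coded 0/1 with the
    lexicographically first level as reference.
    """
    cols = ["class_imbalance"] + [f for f in factor_names if f != "class_imbalance"]
    X = [np.ones(len(table))]
    names = ["intercept"]
    scales: dict[str, tuple[float, float]] = {}
    for c in cols:
        if c not in table.columns:
            raise KeyError(f"covariate {c!r} not in table")
        v = table[c]
        if v.dtype == object or str(v.dtype) == "category":
            levels = sorted(v.unique())
            if len(levels) == 1:
                raise ValueError(f"covariate {c!r} has a single level")
            if len(levels) > 2:
                raise ValueError(f"covariate {c!r} has >2 levels: {levels}")
            x = (v == levels[1]).to_numpy(float)
            names.append(f"{c}[{levels[1]}]")
            scales[c] = (0.0, 1.0)
        else:
            x = v.to_numpy(float)
            if np.ptp(x) == 0:
                raise ValueError(f"covariate {c!r} is constant")
            if standardize:
                mu, sd = float(x.mean()), float(x.std(ddof=0))
                x = (x - mu) / sd
                scales[c] = (mu, sd)
            else:
                scales[c] = (0.0, 1.0)
            names.append(c)
        X.append(x)
    return np.column_stack(X), names, scales


# ----------------------------------------------------------------------
# Laplace-approximate ML fit
# ----------------------------------------------------------------------


@dataclass
class GLMMFit:
    factor_names: list[str]
    coef_names: list[str]
    beta: np.ndarray  # on the (possibly standardized) fitting scale
    se: np.ndarray
    p_values: np.ndarray
    beta_raw: np.ndarray  # back-transformed to the original covariate scale
    sigma_s_sq: float
    sigma_m_sq: float
    loglik: float
    aic: float
    converged: bool
    n_rows: int
    random_effects: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def combined_variance(self) -> float:
        return self.sigma_s_sq + self.sigma_m_sq

    def wald_ci(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.beta - z * self.se, self.beta + z * self.se])


def _binom_loglik(y, n, eta):
    # log C(n, y) + y*eta - n*log(1 + e^eta)
    return float(
        np.sum(
            special.gammaln(n + 1)
            - special.gammaln(y + 1)
            - special.gammaln(n - y + 1)
            + y * eta
            - n * np.logaddexp(0.0, eta)
        )
    )


class _LaplaceEngine:
    """Profiled Laplace log-likelihood for one design.

    Caches the random-effect mode between outer-optimizer evaluations
    (warm starts cut the Newton iterations roughly in half).
    """

    def __init__(self, X, y, n, s_idx, m_idx, S, M):
        self.X, self.y, self.n = X, y, n
        self.s_idx, self.m_idx = s_idx, m_idx
        self.S, self.M = S, M
        self.q = S + M
        self.u_warm = np.zeros(self.q)
        # incidence matrix Z (rows x q)
        rows = np.arange(len(y))
        Z = np.zeros((len(y), self.q))
        Z[rows, s_idx] = 1.0
        Z[rows, M * 0 + S + m_idx] = 1.0
        self.Z = Z

    def _mode(self, beta, d_inv):
        """Damped Newton search for the joint random-effect mode."""
        u = self.u_warm.copy()
        xb = self.X @ beta
        for _ in range(100):
            eta = xb + u[self.s_idx] + u[self.S + self.m_idx]
            pi = special.expit(eta)
            g = self.Z.T @ (self.y - self.n * pi) - d_inv * u
            if np.max(np.abs(g)) < 1e-10:
                break
            w = self.n * pi * (1.0 - pi)
            H = (self.Z.T * w) @ self.Z
            H[np.diag_indices_from(H)] += d_inv
            step = np.linalg.solve(H, g)
            f0 = _binom_loglik(self.y, self.n, eta) - 0.5 * np.sum(d_inv * u**2)
            t = 1.0
            for _ in range(30):
                u_new = u + t * step
                eta_new = xb + u_new[self.s_idx] + u_new[self.S + self.m_idx]
                f1 = _binom_loglik(self.y, self.n, eta_new) - 0.5 * np.sum(
                    d_inv * u_new**2
                )
                if f1 >= f0 - 1e-12:
                    break
                t *= 0.5
            u = u + t * step
        self.u_warm = u
        return u

    def loglik(self, beta, sigma_s_sq, sigma_m_sq):
        d = np.concatenate(
            [np.full(self.S, sigma_s_sq), np.full(self.M, sigma_m_sq)]
        )
        d_inv = 1.0 / d
        u = self._mode(beta, d_inv)
        eta = self.X @ beta + u[self.s_idx] + u[self.S + self.m_idx]
        pi = special.expit(eta)
        w = self.n * pi * (1.0 - pi)
        # log det(I + D Z'WZ) via the symmetrized form
        A = (self.Z.T * w) @ self.Z
        A = A * np.sqrt(d)[:, None] * np.sqrt(d)[None, :]
        A[np.diag_indices_from(A)] += 1.0
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0:  # pragma: no cover - defensive
            return -np.inf, u
        ll = (
            _binom_loglik(self.y, self.n, eta)
            - 0.5 * np.sum(d_inv * u**2)
            - 0.5 * logdet
        )
        return ll, u

    def neg_loglik_packed(self, theta, k):
        beta = theta[:k]
        ss, sm = np.exp(2.0 * theta[k]), np.exp(2.0 * theta[k + 1])
        ll, _ = self.loglik(beta, ss, sm)
        return -ll


_LOG_SIGMA_BOUNDS = (-6.0, 2.5)  # sigma in [~0.0025, ~12]


def fit_glmm(
    table: pd.DataFrame,
    factor_names: list[str] | None = None,
    standardize: bool = True,
    max_restarts: int = 5,
) -> GLMMFit:
    """ML fit of the crossed random-intercept grouped-binomial model.

    ``factor_names`` lists the study factors beyond class imbalance (which
    is always included); ``None`` fits the imbalance-only null model.
    """
    factor_names = list(factor_names or [])
    _validate_table(table)
    studies = sorted(table["study_id"].unique())
    methods = sorted(table["method_id"].unique())
    if len(studies) < 2 or len(methods) < 2:
        raise ValueError("need >= 2 studies and >= 2 methods")
    X, coef_names, scales = _design(table, factor_names, standardize)
    y = table["successes"].to_numpy(float)
    n = table["trials"].to_numpy(float)
    s_idx = table["study_id"].map({s: i for i, s in enumerate(studies)}).to_numpy()
    m_idx = table["method_id"].map({m: i for i, m in enumerate(methods)}).to_numpy()
    engine = _LaplaceEngine(X, y, n, s_idx, m_idx, len(studies), len(methods))
    k = X.shape[1]

    # starting values: aggregate logistic fit, moderate variances
    import statsmodels.api as sm

    glm = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial())
    try:
        beta0 = glm.fit().params
    except Exception:  # pragma: no cover - degenerate start
        beta0 = np.zeros(k)
    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts):
        theta0 = np.concatenate([beta0, [np.log(0.3), np.log(0.3)]])
        if attempt:
            theta0 += rng.normal(0.0, 0.3 * attempt, len(theta0))
            theta0[k:] = np.clip(theta0[k:], *_LOG_SIGMA_BOUNDS)
        engine.u_warm = np.zeros(engine.q)
        res = optimize.minimize(
            engine.neg_loglik_packed,
            theta0,
            args=(k,),
            method="L-BFGS-B",
            bounds=[(None, None)] * k + [_LOG_SIGMA_BOUNDS] * 2,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - 1e-8:
            best = res
        if res.success:
            break
    if best is None or not np.isfinite(best.fun):  # pragma: no cover
        raise RuntimeError("GLMM optimization failed on all restarts")
    theta = best.x
    beta = theta[:k]
    ss, sm_ = float(np.exp(2 * theta[k])), float(np.exp(2 * theta[k + 1]))
    ll, u = engine.loglik(beta, ss, sm_)

    # Wald SEs from the numerical Hessian of the Laplace log-likelihood
    from statsmodels.tools.numdiff import approx_hess1

    hess = approx_hess1(theta, engine.neg_loglik_packed, args=(k,))
    se = np.full(k, np.nan)
    try:
        cov = np.linalg.pinv(hess)
        d = np.diag(cov)[:k]
        se = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:  # pragma: no cover
        pass
    zstat = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))

    # back-transform coefficients to the raw covariate scale
    beta_raw = beta.copy()
    offset = 0.0
    for j, name in enumerate(coef_names):
        base = name.split("[")[0]
        if base in scales and j > 0:
            mu, sd = scales[base]
            beta_raw[j] = beta[j] / sd
            offset += beta[j] * mu / sd
    beta_raw[0] = beta[0] - offset

    aic = -2.0 * ll + 2.0 * (k + 2)
    return GLMMFit(
        factor_names=factor_names,
        coef_names=coef_names,
        beta=beta,
        se=se,
        p_values=pvals,
        beta_raw=beta_raw,
        sigma_s_sq=ss,
        sigma_m_sq=sm_,
        loglik=float(ll),
        aic=float(aic),
        converged=bool(best.success),
        n_rows=len(table),
        random_effects={
            "study": u[: len(studies)],
            "method": u[len(studies):],
        },
    )


# ----------------------------------------------------------------------
# explained variation, forward selection, jackknife
# ----------------------------------------------------------------------


@dataclass
class ExplainedVariation:
    factor: str
    var_l: float
    sigma_sq_null: float
    sigma_sq_factor: float


def explained_variation(null_fit: GLMMFit, factor_fit: GLMMFit) -> ExplainedVariation:
    """Proportional reduction in combined random-intercept variance."""
    if null_fit.n_rows != factor_fit.n_rows:
        raise ValueError("fits are not on the same table")
    s_null = null_fit.combined_variance
    if s_null <= 0:
        raise ValueError("null model has zero combined variance; var_l undefined")
    s_fac = factor_fit.combined_variance
    name = ",".join(factor_fit.factor_names) or "(null)"
    return ExplainedVariation(name, (s_null - s_fac) / s_null, s_null, s_fac)


def _usable_candidates(table: pd.DataFrame, candidates: list[str]) -> list[str]:
    """Drop factors that are constant in this table (unevaluable), with a log."""
    import logging

    usable = []
    for c in candidates:
        if c not in table.columns:
            raise KeyError(f"candidate {c!r} not in table")
        if table[c].nunique() < 2:
            logging.getLogger("exprbench").warning(
                "candidate %r has a single level in this table; skipped", c
            )
            continue
        usable.append(c)
    return usable


def univariable_scan(
    table: pd.DataFrame,
    candidates: list[str] | None = None,
    null_fit: GLMMFit | None = None,
) -> pd.DataFrame:
    """One imbalance-corrected fit per candidate factor, sorted by var_l.

    Candidates constant in this table are skipped (logged), since a
    single-level factor cannot enter the regression.
    """
    candidates = _usable_candidates(table, list(candidates or DEFAULT_CANDIDATES))
    null_fit = null_fit or fit_glmm(table, [])
    rows = []
    for f in candidates:
        fit_f = fit_glmm(table, [f])
        ev = explained_variation(null_fit, fit_f)
        rows.append(
            {
                "factor": f,
                "coef": fit_f.beta_raw[-1],
                "coef_std": fit_f.beta[-1],
                "p_value": fit_f.p_values[-1],
                "aic": fit_f.aic,
                "var_l": ev.var_l,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("var_l", ascending=False).reset_index(drop=True)
    )


@dataclass
class SelectionTrace:
    steps: list[dict]
    selected: list[str]
    null_aic: float
    final_aic: float


def forward_select(
    table: pd.DataFrame,
    candidates: list[str] | None = None,
) -> tuple[SelectionTrace, GLMMFit]:
    """AIC forward selection from the imbalance-only null model.

    At each step the candidate whose addition minimizes AIC enters if the
    AIC strictly decreases; otherwise selection stops.  Returns the trace
    and the final fit (the null fit if nothing enters).
    """
    candidates = _usable_candidates(table, list(candidates or DEFAULT_CANDIDATES))
    if not candidates:
        raise ValueError("need >= 1 (non-constant) candidate factor")
    current_fit = fit_glmm(table, [])
    null_aic = current_fit.aic
    selected: list[str] = []
    steps: list[dict] = []
    remaining = list(candidates)
    while remaining:
        trials = {}
        fits = {}
        for f in remaining:
            fit_f = fit_glmm(table, selected + [f])
            trials[f] = fit_f.aic
            fits[f] = fit_f
        best_f = min(trials, key=lambda f: (trials[f], remaining.index(f)))
        step = {
            "step": len(steps) + 1,
            "candidate_aics": dict(trials),
            "current_aic": current_fit.aic,
        }
        if trials[best_f] < current_fit.aic:
            selected.append(best_f)
            remaining.remove(best_f)
            current_fit = fits[best_f]
            step["chosen"] = best_f
            step["new_aic"] = current_fit.aic
            steps.append(step)
        else:
            step["chosen"] = None
            steps.append(step)
            break
    return (
        SelectionTrace(
            steps=steps,
            selected=selected,
            null_aic=null_aic,
            final_aic=current_fit.aic,
        ),
        current_fit,
    )


@dataclass
class JackknifeReport:
    per_study: pd.DataFrame  # left_out, selected set, univariable p-values
    full_selected: list[str]
    agreement: float
    n_failed: int


def jackknife(
    table: pd.DataFrame,
    candidates: list[str] | None = None,
    full_selected: list[str] | None = None,
) -> JackknifeReport:
    """Leave-one-study-out stability of the forward-selected factor set."""
    candidates = list(candidates or DEFAULT_CANDIDATES)
    studies = sorted(table["study_id"].unique())
    if len(studies) < 3:
        raise ValueError("need >= 3 studies for the jackknife")
    if full_selected is None:
        full_trace, _ = forward_select(table, candidates)
        full_selected = full_trace.selected
    rows = []
    n_failed = 0
    for s in studies:
        sub = table[table["study_id"] != s]
        row: dict = {"left_out": s}
        try:
            null_fit = fit_glmm(sub, [])
            scan = univariable_scan(sub, candidates, null_fit=null_fit)
            for _, r in scan.iterrows():
                row[f"p_{r['factor']}"] = r["p_value"]
            trace, _ = forward_select(sub, candidates)
            row["selected"] = ",".join(trace.selected)
            row["agrees"] = set(trace.selected) == set(full_selected)
            row["converged"] = True
        except (RuntimeError, ValueError) as err:
            row["selected"] = ""
            row["agrees"] = False
            row["converged"] = False
            row["error"] = str(err)
            n_failed += 1
        rows.append(row)
    per_study = pd.DataFrame(rows)
    agreement = float(per_study["agrees"].mean())
    return JackknifeReport(
        per_study=per_study,
        full_selected=list(full_selected),
        agreement=agreement,
        n_failed=n_failed,
    )
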