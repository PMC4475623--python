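"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive: direct enumeration or quadrature,
written without reference to the library code it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import special


def bh_bruteforce(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg by direct evaluation of every cutoff.

    Rejects the k smallest p-values for the largest k with
    p_(k) <= k * alpha / m; returns a boolean mask in original order.
    """
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    mask = np.zeros(m, bool)
    mask[order[:k_star]] = True
    return mask


def loocv_tune_bruteforce(study, spec, fit_fn, rank_fn, seed=0):
    """Exhaustive inner-LOOCV tuning, written independently.

    For every (top_p, params) grid point, leaves each sample out in turn,
    re-ranks probesets on the remainder, fits, and counts errors; returns
    the winner with ties to smaller top_p then earlier params.
    """
    n = study.n_samples
    results = {}
    for top_p in spec.top_p_grid:
        for pi, params in enumerate(spec.grid_points()):
            errs = 0
            for i in range(n):
                keep = [j for j in range(n) if j != i]
                inner = study.subset_samples(np.array(keep))
                ranked = rank_fn(inner, top_p)
                model = fit_fn(
                    spec,
                    inner.subset_probesets(ranked).matrix.T,
                    inner.labels,
                    params,
                    probeset_ids=ranked,
                    seed=seed,
                )
                x = study.subset_probesets(ranked).matrix[:, i]
                errs += int(model.predict(x[None, :])[0] != study.labels[i])
            results[(top_p, pi)] = errs
    best = min(results, key=lambda k: (results[k], k[0], k[1]))
    return best[0], spec.grid_points()[best[1]], results[best]


def glmm_loglik_quadrature(
    beta, sigma_s_sq, sigma_m_sq, X, y, n, s_idx, m_idx, S, M, nodes=40
):
    """Marginal grouped-binomial log-likelihood by Gauss-Hermite quadrature.

    Integrates the M method effects on an outer product grid and, for each
    grid point, the S study effects by independent 1-D quadrature (given
    the method effects, studies factorize).  Exact up to quadrature error;
    intended for S<=4, M<=2.
    """
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(nodes)  # weight e^{-x^2/2}
    gh_w = gh_w / np.sqrt(2 * np.pi)
    xb = X @ beta

    def cell_loglik(s, m, u, v):
        rows = np.flatnonzero((s_idx == s) & (m_idx == m))
        eta = xb[rows] + u + v
        return np.sum(
            special.gammaln(n[rows] + 1)
            - special.gammaln(y[rows] + 1)
            - special.gammaln(n[rows] - y[rows] + 1)
            + y[rows] * eta
            - n[rows] * np.logaddexp(0.0, eta)
        )

    sd_s, sd_m = np.sqrt(sigma_s_sq), np.sqrt(sigma_m_sq)
    total = 0.0
    log_terms = []
    for v_combo in itertools.product(range(nodes), repeat=M):
        v = np.array([gh_x[j] * sd_m for j in v_combo])
        log_w = float(np.sum([np.log(gh_w[j]) for j in v_combo]))
        log_p = log_w
        for s in range(S):
            # 1-D quadrature over u_s
            vals = np.array(
                [
                    np.log(gh_w[a])
                    + np.sum(
                        [cell_loglik(s, m, gh_x[a] * sd_s, v[m]) for m in range(M)]
                    )
                    for a in range(nodes)
                ]
            )
            log_p += special.logsumexp(vals)
        log_terms.append(log_p)
    return float(special.logsumexp(log_terms))


def max_margin_2d_bruteforce(X, y01, n_angles=3600):
    """Maximum-margin separating line for separable 2-D data by angle scan.

    Returns (w, b) with ||w|| = 1 such that w.x + b > 0 for class 1.  The
    optimal direction is found by scanning angles densely and placing the
    boundary midway between the closest projections of the two classes.
    """
    best = None
    for theta in np.linspace(0.0, np.pi, n_angles, endpoint=False):
        w = np.array([np.cos(theta), np.sin(theta)])
        proj = X @ w
        for sign in (1.0, -1.0):
            p = sign * proj
            lo = p[y01 == 1].min()
            hi = p[y01 == 0].max()
            margin = (lo - hi) / 2.0
            if best is None or margin > best[0]:
                best = (margin, sign * w, -(lo + hi) / 2.0 * 1.0)
    margin, w, b = best
    return w, b, margin
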