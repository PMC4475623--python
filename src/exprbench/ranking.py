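"""Moderated t-statistics and FDR-controlled differential expression.

The moderated t shrinks each probeset's pooled two-sample variance toward a
common prior variance estimated across the whole probeset ensemble by
empirical Bayes.  With per-probeset residual df d_g = n - 2, sample variance
s_g^2, and prior (d0, s0^2):

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_g    = (mean1_g - mean2_g) / (s~_g * sqrt(1/n1 + 1/n2))

with t_g ~ t(d0 + d_g) under the null.  The hyperparameters are estimated
by moment matching on e_g = log s_g^2, whose mean and variance under the
scaled-F sampling model involve digamma/trigamma terms; the trigamma
equation is inverted by Newton's method.  A non-positive moment estimate
yields d0 = inf (full shrinkage to s0^2).

Differential-expression counts use the Benjamini-Hochberg step-up procedure
at a configurable FDR level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .study import ExpressionStudy

__all__ = [
    "ModeratedTResult",
    "DEGResult",
    "moderated_t",
    "rank_probesets",
    "count_deg",
]


@dataclass
class ModeratedTResult:
    probeset_ids: list[str]
    mean_diff: np.ndarray
    pooled_sd: np.ndarray
    t_mod: np.ndarray
    df_total: float
    p_value: np.ndarray
    d0: float
    s0_sq: float


@dataclass
class DEGResult:
    adjusted_p: np.ndarray
    rejected: np.ndarray
    n_rejected: int
    alpha: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0_sq) from sample variances.

    Under s_g^2 ~ s0^2 * F(df, d0), e_g = log s_g^2 has
      E[e]   = log s0^2 + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2)
      Var[e] = psi'(df/2) + psi'(d0/2).
    """
    s2 = np.asarray(s2, dtype=float)
    if np.all(s2 <= 0):
        raise ValueError("all sample variances are zero")
    e = np.log(np.maximum(s2, 1e-300))
    g = len(e)
    if g < 2:
        raise ValueError("need >= 2 probesets to estimate the prior")
    emean = e.mean()
    evar = np.sum((e - emean) ** 2) / (g - 1)
    evar -= special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(
            emean
            - special.polygamma(0, df / 2.0)
            + np.log(df / 2.0)
            + special.polygamma(0, d0 / 2.0)
            - np.log(d0 / 2.0)
        )
    else:
        # no excess dispersion beyond chi^2 sampling noise: full shrinkage
        d0 = np.inf
        s0_sq = s2.mean()
    return float(d0), float(s0_sq)


def moderated_t(
    study: ExpressionStudy, d0: float | None = None, s0_sq: float | None = None
) -> ModeratedTResult:
    """Two-sided moderated t-test of every probeset between the two classes.

    ``d0``/``s0_sq`` may be forced (e.g. 0 for the ordinary pooled t,
    ``np.inf`` for full shrinkage); by default both are estimated from the
    data.  Forcing d0 without s0_sq estimates s0_sq from the ensemble.
    """
    m1, m2 = study.class_masks()
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each class needs >= 2 samples (got {n1}, {n2})")
    if study.n_probesets < 2:
        raise ValueError("need >= 2 probesets for prior estimation")
    x1, x2 = study.matrix[:, m1], study.matrix[:, m2]
    mean_diff = x1.mean(axis=1) - x2.mean(axis=1)
    dg = n1 + n2 - 2
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / dg
    if np.all(s2 <= 0):
        raise ValueError("all probeset variances are zero")
    if d0 is None:
        d0_est, s0_est = estimate_prior(s2, dg)
    else:
        d0_est = float(d0)
        s0_est = estimate_prior(s2, dg)[1] if s0_sq is None else float(s0_sq)
    if s0_sq is not None:
        s0_est = float(s0_sq)
    if np.isinf(d0_est):
        s2_tilde = np.full_like(s2, s0_est)
    elif d0_est == 0:
        s2_tilde = s2
    else:
        s2_tilde = (d0_est * s0_est + dg * s2) / (d0_est + dg)
    # total df capped at the ensemble-wide residual df (finite even at d0=inf)
    df_total = float(min(d0_est + dg, study.n_probesets * dg))
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / se
    t = np.where(se > 0, t, np.inf * np.sign(mean_diff))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return ModeratedTResult(
        probeset_ids=list(study.probeset_ids),
        mean_diff=mean_diff,
        pooled_sd=np.sqrt(s2),
        t_mod=t,
        df_total=df_total,
        p_value=p,
        d0=d0_est,
        s0_sq=s0_est,
    )


def rank_probesets(result: ModeratedTResult, k: int) -> list[str]:
    """Top-k probeset ids by |moderated t|, ties broken lexicographically."""
    p = len(result.probeset_ids)
    if not (1 <= k <= p):
        raise ValueError(f"k={k} must lie in [1, {p}]")
    order = sorted(range(p), key=lambda i: (-abs(result.t_mod[i]), result.probeset_ids[i]))
    return [result.probeset_ids[i] for i in order[:k]]


def count_deg(result: ModeratedTResult, alpha: float = 0.05) -> DEGResult:
    """Benjamini-Hochberg step-up at FDR ``alpha`` on the moderated-t p-values."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    rejected, adj_p, _, _ = multipletests(result.p_value, alpha=alpha, method="fdr_bh")
    return DEGResult(
        adjusted_p=adj_p,
        rejected=rejected,
        n_rejected=int(rejected.sum()),
        alpha=alpha,
    )
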