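"""Per-study predictive factors.

Six study-level quantities are extracted from each (filtered) expression
study and later used as covariates in the accuracy meta-regression:

* ``pDEG``       count of probesets differentially expressed at FDR 5%
                 (moderated t + Benjamini-Hochberg), entered on the log2
                 scale as ``log2(pDEG + 1)`` so that zero counts stay
                 defined;
* ``fc``         mean absolute standardized fold change: per probeset
                 |mean1 - mean2| / pooled SD, averaged over probesets;
* ``withincor``  mean absolute off-diagonal entry of a shrinkage-estimated
                 within-class correlation matrix, averaged over the two
                 classes;
* ``sample_size`` and ``class_imbalance`` (majority fraction);
* ``medical_question`` (diagnostic / non-diagnostic) and ``cell_type``
  (blood / non-blood) from study metadata.

The correlation shrinkage is linear toward the identity with the analytic
intensity  lambda* = sum Var_hat(r_ij) / sum r_ij^2  over off-diagonal
pairs, clamped to [0, 1]; shrunk correlations are (1 - lambda*) r_ij.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .ranking import count_deg, moderated_t
from .study import ExpressionStudy

__all__ = [
    "StudyFactors",
    "compute_fc",
    "compute_withincor",
    "compute_pdeg",
    "compute_imbalance",
    "compute_factors",
    "factors_table",
    "FACTOR_COLUMNS",
]

FACTOR_COLUMNS = [
    "study_id",
    "pDEG",
    "log2_pDEG",
    "fc",
    "withincor",
    "sample_size",
    "class_imbalance",
    "medical_question",
    "cell_type",
]


@dataclass
class StudyFactors:
    study_id: str
    pDEG: int
    log2_pDEG: float
    fc: float
    withincor: float
    sample_size: int
    class_imbalance: float
    medical_question: str
    cell_type: str

    def to_dict(self) -> dict:
        return asdict(self)


def compute_fc(study: ExpressionStudy) -> float:
    """Mean absolute standardized mean difference across probesets."""
    m1, m2 = study.class_masks()
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("both classes need >= 2 samples")
    x1, x2 = study.matrix[:, m1], study.matrix[:, m2]
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    pooled_sd = np.sqrt(ss / (n1 + n2 - 2))
    if np.any(pooled_sd == 0):
        bad = study.probeset_ids[int(np.argmax(pooled_sd == 0))]
        raise ValueError(f"zero pooled SD for probeset {bad!r}")
    return float(np.mean(np.abs(x1.mean(axis=1) - x2.mean(axis=1)) / pooled_sd))


def _shrinkage_intensity(x: np.ndarray) -> float:
    """Analytic linear-shrinkage intensity for a correlation matrix.

    ``x`` is (probesets x samples) for one class.  Off-diagonal sums of the
    estimated sampling variance of r_ij over r_ij^2, clamped to [0, 1].
    """
    p, n = x.shape
    xs = x - x.mean(axis=1, keepdims=True)
    sd = xs.std(axis=1, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    xs = xs / sd[:, None]  # standardized: rows have sum of squares n-1
    r = (xs @ xs.T) / (n - 1)
    # Var_hat(r_ij) = n/(n-1)^3 * sum_k (w_kij - mean_w)^2, w_kij = xs_ki xs_kj
    m1 = xs @ xs.T  # sum_k w_kij
    m2 = (xs**2) @ (xs**2).T  # sum_k w_kij^2
    var_r = n / (n - 1.0) ** 3 * (m2 - m1**2 / n)
    mask = ~np.eye(p, dtype=bool)
    denom = float((r[mask] ** 2).sum())
    if denom == 0:
        return 1.0
    return float(min(1.0, max(0.0, var_r[mask].sum() / denom)))


def compute_withincor(
    study: ExpressionStudy, shrinkage_intensity: float | None = None
) -> float:
    """Average absolute shrunk within-class correlation.

    Per class, pairwise Pearson correlations are shrunk toward zero by the
    analytic intensity (or a forced one); the mean |r| over the strict
    upper triangle is computed, and the two class values are averaged.
    """
    if study.n_probesets < 2:
        raise ValueError("need >= 2 probesets")
    vals = []
    for mask in study.class_masks():
        if mask.sum() < 3:
            raise ValueError("both classes need >= 3 samples")
        x = study.matrix[:, mask]
        lam = (
            _shrinkage_intensity(x)
            if shrinkage_intensity is None
            else float(shrinkage_intensity)
        )
        sd = x.std(axis=1, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        r = (xs @ xs.T) / (x.shape[1] - 1)
        iu = np.triu_indices(study.n_probesets, k=1)
        vals.append((1.0 - lam) * float(np.mean(np.abs(r[iu]))))
    return float(np.mean(vals))


def compute_pdeg(study: ExpressionStudy, alpha: float = 0.05) -> tuple[int, float]:
    """(pDEG, log2(pDEG + 1)) at FDR level ``alpha``."""
    deg = count_deg(moderated_t(study), alpha=alpha)
    return deg.n_rejected, math.log2(deg.n_rejected + 1)


def compute_imbalance(study: ExpressionStudy) -> float:
    """Majority-class fraction, in [0.5, 1]."""
    n1, n2 = study.class_sizes()
    return max(n1, n2) / (n1 + n2)


def compute_factors(study: ExpressionStudy, alpha: float = 0.05) -> StudyFactors:
    """All factors for one (already filtered) study."""
    pdeg, log2_pdeg = compute_pdeg(study, alpha=alpha)
    return StudyFactors(
        study_id=study.study_id,
        pDEG=pdeg,
        log2_pDEG=log2_pdeg,
        fc=compute_fc(study),
        withincor=compute_withincor(study),
        sample_size=study.n_samples,
        class_imbalance=compute_imbalance(study),
        medical_question=str(study.metadata.get("medical_question", "diagnostic")),
        cell_type=str(study.metadata.get("cell_type", "blood")),
    )


def factors_table(factors: list[StudyFactors]) -> pd.DataFrame:
    """One row per study, columns in the canonical order."""
    return pd.DataFrame([f.to_dict() for f in factors])[FACTOR_COLUMNS]
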