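"""Non-informative probeset filtering.

Two sequential filters produce the working expression data for a study:

1. intensity: keep probesets with log2 expression above a threshold
   (default 5) in at least a fraction (default 10%) of samples;
2. variability: among those, keep probesets whose sample SD exceeds a
   threshold (default 0.5).

"At least ten percent" is read as a ceiling on the count; the SD uses the
n-1 denominator, pooled over all samples of the study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .study import ExpressionStudy

__all__ = ["FilterParams", "FilterReport", "filter_probesets"]


@dataclass(frozen=True)
class FilterParams:
    intensity_threshold: float = 5.0
    min_fraction: float = 0.10
    sd_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.min_fraction <= 1):
            raise ValueError("min_fraction must lie in (0, 1]")
        if not (math.isfinite(self.intensity_threshold) and math.isfinite(self.sd_threshold)):
            raise ValueError("thresholds must be finite")


@dataclass
class FilterReport:
    study_id: str
    n_input: int
    n_removed_intensity: int
    n_removed_sd: int
    n_retained: int
    params: FilterParams

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = asdict(self.params)
        return d


def filter_probesets(
    study: ExpressionStudy, params: FilterParams | None = None
) -> tuple[ExpressionStudy, FilterReport]:
    """Apply the intensity filter, then the SD filter.

    Raises
    ------
    ValueError
        If no probeset survives, naming the stage that emptied the study.
    """
    params = params or FilterParams()
    if study.n_probesets < 1:
        raise ValueError("study has no probesets")
    n = study.n_samples
    min_count = math.ceil(params.min_fraction * n)
    above = (study.matrix > params.intensity_threshold).sum(axis=1)
    keep1 = above >= min_count
    if not keep1.any():
        raise ValueError(
            f"study {study.study_id!r}: empty after filtering at the intensity stage "
            f"(threshold {params.intensity_threshold}, >= {min_count} samples)"
        )
    sds = study.matrix[keep1].std(axis=1, ddof=1)
    keep2 = sds > params.sd_threshold
    if not keep2.any():
        raise ValueError(
            f"study {study.study_id!r}: empty after filtering at the SD stage "
            f"(threshold {params.sd_threshold})"
        )
    kept_ids = [
        pid for pid, k in zip(np.array(study.probeset_ids)[keep1], keep2) if k
    ]
    filtered = study.subset_probesets(kept_ids)
    report = FilterReport(
        study_id=study.study_id,
        n_input=study.n_probesets,
        n_removed_intensity=int((~keep1).sum()),
        n_removed_sd=int((~keep2).sum()),
        n_retained=filtered.n_probesets,
        params=params,
    )
    return filtered, report
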