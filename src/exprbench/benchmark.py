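"""Nested resampling benchmark: outer Monte-Carlo CV, inner leave-one-out.

Protocol per study and classifier:

1. B stratified outer splits put round(2/3) of each class into a learning
   set, the rest into a testing set.
2. On each learning set, probesets are ranked by |moderated t| and the
   tuning grid (top-p count x method parameters) is searched by inner
   leave-one-out CV.  The ranking is recomputed on every inner fold from
   the n-1 retained samples, so no held-out sample ever influences feature
   selection.
3. The classifier is refit on the whole learning set at the winning grid
   point (using the learning-set ranking) and evaluated on the testing
   set; correct/incorrect counts on both sets are recorded.

The aggregate accuracy is the mean over splits of per-split test accuracy;
with constant testing-set size this equals total correct / total classified.

Tie-breaking during tuning: fewest inner misclassifications wins; ties go
to the smaller top-p, then to the earlier grid point in the classifier spec's
documented parameter order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, FittedModel, fit
from .ranking import moderated_t, rank_probesets
from .study import ExpressionStudy

__all__ = [
    "SplitPlan",
    "SplitRecord",
    "BenchmarkResult",
    "make_splits",
    "tune_inner",
    "run_benchmark",
    "run_suite_benchmark",
    "benchmark_to_frame",
]


@dataclass(frozen=True)
class SplitPlan:
    """Outer resampling plan: B stratified 2/3 - 1/3 splits."""

    B: int = 100
    learning_fraction: float = 2.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not (0 < self.learning_fraction < 1):
            raise ValueError("learning_fraction must lie in (0, 1)")


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def make_splits(
    study: ExpressionStudy, plan: SplitPlan
) -> list[tuple[np.ndarray, np.ndarray]]:
    """B stratified (learning, testing) index partitions.

    Per class k, round(learning_fraction * n_k) samples (round half up) go
    to the learning set, clipped so both sides keep at least one sample of
    each class.  Reproducible from the plan seed; split b uses the seed
    pair (plan.seed, b).
    """
    masks = study.class_masks()
    for m in masks:
        if m.sum() < 3:
            raise ValueError(
                "need >= 3 samples per class for a stratified 2/3 - 1/3 split"
            )
    splits = []
    for b in range(plan.B):
        rng = np.random.default_rng([plan.seed, b])
        learn, test = [], []
        for m in masks:
            idx = np.flatnonzero(m)
            nk = len(idx)
            n_learn = min(max(_round_half_up(plan.learning_fraction * nk), 1), nk - 1)
            perm = rng.permutation(idx)
            learn.append(perm[:n_learn])
            test.append(perm[n_learn:])
        splits.append((np.sort(np.concatenate(learn)), np.sort(np.concatenate(test))))
    return splits


def _feasible_top_p(spec: ClassifierSpec, p_avail: int, n_learn: int) -> list[int]:
    """Grid of top-p counts usable for this method on this learning set.

    LDA/DLDA need p < n for an invertible pooled covariance; their grid is
    restricted to p <= n_learn - 3 (one sample is further held out in the
    inner LOOCV).  Counts beyond the available probesets are dropped; if
    nothing survives, the smallest feasible count is used.
    """
    grid = [k for k in spec.top_p_grid if k <= p_avail]
    if spec.name in ("LDA", "DLDA"):
        grid = [k for k in grid if k <= n_learn - 3]
    if not grid:
        grid = [min(2, p_avail)] if spec.name in ("LDA", "DLDA") else [min(5, p_avail)]
    return grid


def tune_inner(
    spec: ClassifierSpec,
    learning: ExpressionStudy,
    seed: int = 0,
) -> tuple[int, dict[str, Any], int]:
    """Select (top-p, params) by inner leave-one-out CV on the learning set.

    Returns (best_top_p, best_params, inner_error_count).  With a
    single-point grid the point is returned without running LOOCV.
    """
    n = learning.n_samples
    top_p_grid = _feasible_top_p(spec, learning.n_probesets, n)
    param_points = spec.grid_points()
    if not param_points:
        raise ValueError("empty tuning grid")
    if len(top_p_grid) == 1 and len(param_points) == 1:
        return top_p_grid[0], param_points[0], -1

    max_p = max(top_p_grid)
    errors = np.zeros((len(top_p_grid), len(param_points)), dtype=int)
    y = learning.labels
    for i in range(n):
        keep = np.setdiff1d(np.arange(n), [i])
        inner = learning.subset_samples(keep)
        if min(inner.class_sizes()) < 2:
            continue
        ranked = rank_probesets(moderated_t(inner), min(max_p, inner.n_probesets))
        pos = {p: j for j, p in enumerate(inner.probeset_ids)}
        rows = np.array([pos[p] for p in ranked])
        X_in = inner.matrix[rows].T  # (n-1, max_p) in ranked order
        x_out = learning.matrix[[pos[p] for p in ranked], i]
        for a, tp in enumerate(top_p_grid):
            for c, params in enumerate(param_points):
                model = fit(
                    spec, X_in[:, :tp], inner.labels, params,
                    probeset_ids=ranked[:tp], seed=seed,
                )
                pred = model.predict(x_out[:tp][None, :])[0]
                errors[a, c] += int(pred != y[i])
    best = np.unravel_index(np.argmin(errors), errors.shape)  # row-major:
    # smallest top-p first, then earliest param point — the documented order
    return top_p_grid[best[0]], param_points[best[1]], int(errors[best])


@dataclass
class SplitRecord:
    split: int
    chosen_p: int
    chosen_params: dict[str, Any]
    learn_correct: int
    learn_total: int
    test_correct: int
    test_total: int
    error: str | None = None


@dataclass
class BenchmarkResult:
    """Per-split records and aggregate accuracy for one (study, classifier)."""

    study_id: str
    classifier: str
    records: list[SplitRecord] = field(default_factory=list)

    @property
    def acc(self) -> float:
        """Mean over splits of per-split test accuracy."""
        ok = [r for r in self.records if r.error is None]
        if not ok:
            raise ValueError(
                f"{self.classifier} failed on every split of {self.study_id}"
            )
        return float(np.mean([r.test_correct / r.test_total for r in ok]))

    @property
    def test_correct_total(self) -> int:
        return sum(r.test_correct for r in self.records if r.error is None)

    @property
    def test_total(self) -> int:
        return sum(r.test_total for r in self.records if r.error is None)

    @property
    def n_failed_splits(self) -> int:
        return sum(1 for r in self.records if r.error is not None)


def run_benchmark(
    study: ExpressionStudy,
    specs: Sequence[ClassifierSpec],
    plan: SplitPlan,
) -> dict[str, BenchmarkResult]:
    """Run the full nested protocol for every classifier on one study."""
    splits = make_splits(study, plan)
    results = {s.name: BenchmarkResult(study.study_id, s.name) for s in specs}
    for b, (learn_idx, test_idx) in enumerate(splits):
        learning = study.subset_samples(learn_idx)
        testing = study.subset_samples(test_idx)
        split_seed = int(np.random.default_rng([plan.seed, b, 1]).integers(2**31))
        outer_rank_full = moderated_t(learning)
        for spec in specs:
            rec = _run_one_split(
                spec, learning, testing, outer_rank_full, b, split_seed
            )
            results[spec.name].records.append(rec)
    for name, res in results.items():
        if res.n_failed_splits == len(res.records):
            first = next(r.error for r in res.records)
            raise RuntimeError(
                f"classifier {name} failed on all {len(res.records)} splits of "
                f"study {study.study_id}: {first}"
            )
    return results


def _run_one_split(spec, learning, testing, outer_rank, b, seed) -> SplitRecord:
    try:
        top_p, params, _ = tune_inner(spec, learning, seed=seed)
        ranked = rank_probesets(outer_rank, top_p)
        sub = learning.subset_probesets(ranked)
        model = fit(
            spec, sub.matrix.T, learning.labels, params,
            probeset_ids=ranked, seed=seed,
        )
        test_sub = testing.subset_probesets(ranked)
        pred_test = model.predict(test_sub.matrix.T)
        pred_learn = model.predict(sub.matrix.T)
        return SplitRecord(
            split=b,
            chosen_p=top_p,
            chosen_params=params,
            learn_correct=int((pred_learn == learning.labels).sum()),
            learn_total=learning.n_samples,
            test_correct=int((pred_test == testing.labels).sum()),
            test_total=testing.n_samples,
        )
    except (ValueError, KeyError) as err:
        return SplitRecord(
            split=b, chosen_p=0, chosen_params={}, learn_correct=0,
            learn_total=0, test_correct=0, test_total=0, error=str(err),
        )


def run_suite_benchmark(
    studies: Sequence[ExpressionStudy],
    specs: Sequence[ClassifierSpec],
    plan: SplitPlan,
) -> dict[tuple[str, str], BenchmarkResult]:
    """Benchmark every classifier on every study; keys are (study, method)."""
    out: dict[tuple[str, str], BenchmarkResult] = {}
    for study in studies:
        res = run_benchmark(study, specs, plan)
        for name, r in res.items():
            out[(study.study_id, name)] = r
    return out


def benchmark_to_frame(
    results: dict[tuple[str, str], BenchmarkResult] | dict[str, BenchmarkResult],
) -> pd.DataFrame:
    """Flatten per-split records into a tidy frame (one row per split)."""
    rows = []
    for res in results.values():
        for r in res.records:
            rows.append(
                {
                    "study_id": res.study_id,
                    "classifier": res.classifier,
                    "split": r.split,
                    "chosen_p": r.chosen_p,
                    "chosen_params": str(r.chosen_params),
                    "learn_correct": r.learn_correct,
                    "learn_total": r.learn_total,
                    "test_correct": r.test_correct,
                    "test_total": r.test_total,
                    "error": r.error or "",
                }
            )
    return pd.DataFrame(rows)
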