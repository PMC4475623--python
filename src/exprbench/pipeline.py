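"""End-to-end orchestration: simulate -> filter -> benchmark -> factors ->
meta-regression, with every stage's tables written to disk.

The pipeline is driven programmatically (see the ``analysis/`` scripts) via
:class:`PipelineConfig` / :func:`run_pipeline`; each stage consumes the
previous stage's in-memory objects and persists CSV/JSON outputs so any
stage can be re-examined in isolation.  All randomness flows from the
single configured seed.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .benchmark import SplitPlan, benchmark_to_frame, run_suite_benchmark
from .classifiers import (
    CLASSIFIER_NAMES,
    default_grids,
    pointwise_grids,
    reduced_grids,
)
from .factors import compute_factors, factors_table
from .io import read_suite, write_suite
from .metareg import (
    DEFAULT_CANDIDATES,
    build_table,
    explained_variation,
    fit_glmm,
    forward_select,
    jackknife,
    univariable_scan,
)
from .preprocess import FilterParams, filter_probesets
from .simulate import default_suite_configs, simulate_suite

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("exprbench")


@dataclass
class PipelineConfig:
    """Settings for one full run.

    Defaults reproduce the reference protocol: B=100 stratified 2/3-1/3
    outer splits, inner LOOCV tuning over the full grids of all nine
    classifiers, filters at intensity 5 in 10% of samples and SD 0.5, FDR
    5%, and all six study factors as selection candidates.
    """

    out_dir: str = "results/run"
    # data source: simulate a suite unless a manifest of studies is given
    input_manifest: str | None = None
    n_studies: int = 25
    n_probesets: int = 2000
    seed: int = 0
    # benchmark protocol
    B: int = 100
    grid_preset: str = "full"  # full | reduced | pointwise
    classifiers: list[str] = field(default_factory=lambda: list(CLASSIFIER_NAMES))
    # preprocessing & testing
    intensity_threshold: float = 5.0
    min_fraction: float = 0.10
    sd_threshold: float = 0.5
    fdr_alpha: float = 0.05
    # meta-regression
    candidates: list[str] = field(default_factory=lambda: list(DEFAULT_CANDIDATES))
    run_jackknife: bool = True
    write_data: bool = False
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def grids(self) -> dict:
        presets = {
            "full": default_grids,
            "reduced": reduced_grids,
            "pointwise": pointwise_grids,
        }
        if self.grid_preset not in presets:
            raise ValueError(f"grid_preset must be one of {sorted(presets)}")
        all_grids = presets[self.grid_preset]()
        bad = set(self.classifiers) - set(all_grids)
        if bad:
            raise ValueError(f"unknown classifiers: {sorted(bad)}")
        return {name: all_grids[name] for name in self.classifiers}


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage; returns the result bundle and writes tables."""
    logging.basicConfig(stream=sys.stderr, level=config.verbosity)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}

    def _stage(name):
        log.info("stage: %s", name)
        timings[name] = time.time()

    def _done(name):
        timings[name] = round(time.time() - timings[name], 2)

    # -- data ----------------------------------------------------------
    _stage("simulate")
    if config.input_manifest:
        studies = read_suite(config.input_manifest)
    else:
        configs = default_suite_configs(
            config.n_studies, config.n_probesets, suite_seed=config.seed
        )
        studies = simulate_suite(configs)
        if config.write_data:
            write_suite(studies, out / "data")
    _done("simulate")

    # -- preprocessing -------------------------------------------------
    _stage("filter")
    fparams = FilterParams(
        config.intensity_threshold, config.min_fraction, config.sd_threshold
    )
    filtered, reports = [], []
    for st in studies:
        f, rep = filter_probesets(st, fparams)
        filtered.append(f)
        reports.append(rep.to_dict())
    (out / "filter_reports.json").write_text(json.dumps(reports, indent=1))
    _done("filter")

    # -- factors -------------------------------------------------------
    _stage("factors")
    facs = factors_table([compute_factors(st, config.fdr_alpha) for st in filtered])
    facs.to_csv(out / "factors.csv", index=False)
    _done("factors")

    # -- benchmark -----------------------------------------------------
    _stage("benchmark")
    plan = SplitPlan(B=config.B, seed=config.seed)
    results = run_suite_benchmark(filtered, list(config.grids().values()), plan)
    bench = benchmark_to_frame(results)
    bench.to_csv(out / "benchmark_splits.csv", index=False)
    _done("benchmark")

    # -- meta-regression -----------------------------------------------
    table = build_table(bench, facs)
    table.to_csv(out / "accuracy_table.csv", index=False)
    if table["method_id"].nunique() < 2 or table["study_id"].nunique() < 2:
        log.warning("meta-regression skipped: needs >= 2 studies and >= 2 methods")
        run_log = {
            "config": asdict(config),
            "timings_s": timings,
            "total_s": round(time.time() - t_start, 2),
            "versions": _versions(),
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
        return {
            "studies": filtered,
            "factors": facs,
            "benchmark": bench,
            "table": table,
            "run_log": run_log,
        }
    _stage("metareg")
    null_fit = fit_glmm(table, [])
    scan = univariable_scan(table, config.candidates, null_fit=null_fit)
    scan.to_csv(out / "univariable_scan.csv", index=False)
    trace, final_fit = forward_select(table, config.candidates)
    final_ev = explained_variation(null_fit, final_fit).var_l if trace.selected else 0.0
    (out / "forward_selection.json").write_text(
        json.dumps(
            {
                "selected": trace.selected,
                "null_aic": trace.null_aic,
                "final_aic": trace.final_aic,
                "steps": trace.steps,
                "final_explained_variation": final_ev,
                "final_coefficients": dict(
                    zip(final_fit.coef_names, final_fit.beta_raw.tolist())
                ),
                "final_p_values": dict(
                    zip(final_fit.coef_names, final_fit.p_values.tolist())
                ),
                "sigma_s_sq": final_fit.sigma_s_sq,
                "sigma_m_sq": final_fit.sigma_m_sq,
            },
            indent=1,
        )
    )
    _done("metareg")

    jk = None
    if config.run_jackknife:
        _stage("jackknife")
        jk = jackknife(table, config.candidates, full_selected=trace.selected)
        jk.per_study.to_csv(out / "jackknife.csv", index=False)
        _done("jackknife")

    run_log = {
        "config": asdict(config),
        "timings_s": timings,
        "total_s": round(time.time() - t_start, 2),
        "versions": _versions(),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
    return {
        "studies": filtered,
        "factors": facs,
        "benchmark": bench,
        "table": table,
        "null_fit": null_fit,
        "scan": scan,
        "trace": trace,
        "final_fit": final_fit,
        "final_explained_variation": final_ev,
        "jackknife": jk,
        "run_log": run_log,
    }


def _versions() -> dict[str, str]:
    import sklearn
    import scipy
    import statsmodels

    return {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
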