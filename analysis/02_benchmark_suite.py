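"""Benchmark the nine classifiers on the simulated suite.

Runs the nested protocol (B=20 stratified outer splits, inner LOOCV where
a grid has more than one point) with the desk-scale single-point grids,
and writes the aggregated (study x classifier) accuracy table to
results/.  Per-split records go to scratch/ (large).
"""

import sys
from pathlib import Path

from exprbench.benchmark import SplitPlan, benchmark_to_frame, run_suite_benchmark
from exprbench.classifiers import pointwise_grids
from exprbench.io import read_suite
from exprbench.preprocess import filter_probesets

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
B = 20
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    manifest = ROOT / "scratch" / "suite" / "manifest.csv"
    if not manifest.exists():
        raise SystemExit("run analysis/01_simulate_suite.py first")
    studies = [filter_probesets(s)[0] for s in read_suite(manifest)]
    specs = list(pointwise_grids().values())
    results = run_suite_benchmark(studies, specs, SplitPlan(B=B, seed=SEED))
    frame = benchmark_to_frame(results)
    frame.to_csv(ROOT / "scratch" / "benchmark_splits.csv", index=False)
    agg = (
        frame.groupby(["study_id", "classifier"], as_index=False)
        .agg(test_correct=("test_correct", "sum"), test_total=("test_total", "sum"))
    )
    agg["accuracy"] = agg.test_correct / agg.test_total
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    agg.to_csv(out / "benchmark_accuracy.csv", index=False)
    by_clf = agg.groupby("classifier")["accuracy"].mean().sort_values(ascending=False)
    print(f"benchmarked {agg.study_id.nunique()} studies x {by_clf.size} classifiers, B={B}")
    print("mean accuracy by classifier:")
    print(by_clf.round(3).to_string())


if __name__ == "__main__":
    main()
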