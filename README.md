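# exprbench

**What makes a two-class gene-expression study easy or hard to
classify?**  `exprbench` is a simulation-and-analysis package for the
meta-scientific question behind classifier benchmarking: across many
expression studies, which measurable characteristics of the *data* —
rather than of the classifier — drive prediction accuracy?

It provides, as importable library code plus numbered analysis drivers:

* a **generator** of two-class log2 expression studies with controllable
  DE-probeset count, standardized fold change, block-wise within-class
  correlation, sample size and class imbalance — plus two-gene
  "scenario" studies and direct draws from the meta-regression model;
* the **preprocessing filters** (intensity > 5 in ≥10% of samples,
  SD > 0.5) that define the working data;
* **moderated-t ranking** (empirical-Bayes variance shrinkage, verified
  against Bioconductor limma) and Benjamini–Hochberg DE counting;
* **nine classifiers** (LDA, DLDA, nearest shrunken centroids, random
  forest, boosted trees, ridge- and lasso-penalized logistic regression,
  linear SVM, KNN) behind one fit/predict contract with their canonical
  tuning grids;
* a **nested benchmark engine**: B stratified 2/3–1/3 Monte-Carlo outer
  splits with inner leave-one-out tuning that re-ranks probesets on
  every fold (no leakage by construction);
* **study factors**: pDEG (FDR-5% DE count, log2 scale), fc (mean
  standardized fold change), withincor (shrinkage-estimated within-class
  correlation), sample size, class imbalance, and two study annotations;
* a **crossed random-intercept grouped-binomial logistic
  meta-regression** (Laplace ML, validated against `lme4::glmer`), with
  explained variation, AIC forward selection, and a leave-one-study-out
  jackknife.

The model at the core: with u_S, v_M independent Gaussian random
intercepts for study and classification method,

    logit π_SM = (β0 + u_S + v_M) + β1·imbalance_S + β·x_S,

fitted to (correct, classified) counts per (study, method) cell; a
factor's *explained variation* is the proportional reduction it causes
in σ_S² + σ_M² relative to the imbalance-only null model.

See `docs/methods.md` for the full model descriptions, pinned numerical
conventions, and limitations.

## Worked example

Run the analysis drivers in order (each takes a seed, default 0):

```bash
python analysis/01_simulate_suite.py    # 25-study factorial suite + factors
python analysis/02_benchmark_suite.py   # nine classifiers, B=20 nested CV
python analysis/03_meta_regression.py   # which factors explain accuracy?
python analysis/04_scenarios.py         # two-gene correlation scenarios
python analysis/05_model_checks.py      # GLMM calibration checks
```

`01` simulates 25 studies crossing the DE count (2–12) with the
standardized fold change (1.2–3.0) and prints the span of the extracted
factors:

```
25 studies; pDEG spans 1..12, fc spans 0.28..0.44, withincor spans 0.017..0.057
```

`03` then reports, for this suite (seed 0):

```
univariable scan (sorted by explained variation):
          factor     coef  coef_std  p_value       aic  var_l
       log2_pDEG   1.3429    1.0948   0.0000 1675.8482 0.5790
              fc  13.5136    0.6326   0.0149 1691.9616 0.1856
       withincor -34.9760   -0.3536   0.2196 1695.9072 0.0549
     sample_size   0.0464    0.2228   0.4343 1696.7878 0.0262
       cell_type  -0.3736   -0.3736   0.6080 1697.0617 0.0158
medical_question   0.4566    0.4566   0.4645 1696.9417 0.0140

forward selection kept ['log2_pDEG', 'sample_size', 'cell_type', 'fc',
'withincor'] (AIC 1695.4 -> 1672.8); combined explained variation 73.4%
jackknife: selected set reproduced in 14 of 25 leave-one-study-out refits
(robustness 56%)
```

The DE count explains the most between-study variation in accuracy
(58% here), with the fold change second; both carry positive
coefficients.  (Numbers above are from the seed-0 run on this machine;
exact values depend on the seed.  The qualitative result is stable: the DE
count and the fold change dominate the between-study variation in
accuracy, with the within-class correlation as an occasional third
factor — and the two-gene scenarios in `04` show *why* correlation can
help: with opposite fold-change signs, positive within-class correlation
contracts the noise along the discriminant direction, raising held-out
LDA accuracy from ~0.75 at ρ=0 to ~0.99 at ρ=0.9.)

Programmatic use mirrors the scripts:

```python
from exprbench import (StudySimConfig, simulate_study, filter_probesets,
                       SplitPlan, run_benchmark, reduced_grids)

study, _ = filter_probesets(simulate_study(
    StudySimConfig(study_id="demo", n1=30, n2=30, p=500,
                   n_de=50, delta=3.0, seed=5)))
res = run_benchmark(study, [reduced_grids()["SCDA"]], SplitPlan(B=20, seed=1))
print(res["SCDA"].acc)   # 1.0 — a 3-SD, 50-gene signal is trivially separable
```

## Layout

```
src/exprbench/      library (simulation, filtering, ranking, classifiers,
                    benchmark engine, factors, meta-regression, pipeline)
analysis/           numbered drivers reproducing the analyses
tests/              pytest suite incl. property-based acceptance tests
scripts/acceptance.py   headline-quantity reproduction
docs/methods.md     models, conventions, limitations
results/            small CSV/JSON outputs of the analysis drivers
```
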