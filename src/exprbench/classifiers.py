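"""Nine classification functions behind one fit/predict contract.

The benchmark compares methods spanning four families: discriminant /
Bayes-type rules (LDA, DLDA, SCDA), trees (random forest RF, tree-based
boosting TBB), regularized linear models (RIDGE, LASSO, linear SVM) and
nearest neighbours (KNN).  Each has a fixed candidate grid for its tuning
parameter(s) plus a grid of top-ranked probeset counts; the discriminant
rules LDA/DLDA are restricted to very few probesets because their pooled
covariance must be invertible (p < n).

Conventions pinned here (the upstream descriptions leave them open):

* RIDGE/LASSO: penalized logistic log-likelihood  -l(beta) + lam * pen(beta)
  with pen the squared L2 / L1 norm, intercept unpenalized, features
  standardized on the learning set (scikit-learn ``C = 1/lam``).
* RF: the per-split feature count m is a multiplier on sqrt(#features),
  rounded to the nearest integer with floor 1; each tree is grown on a
  with-replacement sample of size ceil(2N/3); 500 trees by default.
* TBB: AdaBoost reweighting over depth-2 classification trees.
* KNN: Euclidean distance; a vote tie goes to the nearest neighbour's
  class; equal distances are broken by learning-sample order.
* A prediction tie at exactly 50/50 class prior (SCDA under full
  shrinkage, degenerate discriminant scores) goes to the lexicographically
  first class label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import linalg as sla
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ClassifierSpec",
    "FittedModel",
    "CLASSIFIER_NAMES",
    "default_grids",
    "reduced_grids",
    "pointwise_grids",
    "fit",
    "predict_from_study",
]

CLASSIFIER_NAMES = ("LDA", "DLDA", "SCDA", "RF", "TBB", "RIDGE", "LASSO", "SVM", "KNN")

#: top-probeset-count candidates for methods without a dimensionality limit
NON_DISCRIMINANT_TOP_P = (5, 10, 15, 20, 25, 50, 55)
#: LDA/DLDA candidates (covariance invertibility requires p < n); for very
#: small studies this reduces further to (2, 3)
DISCRIMINANT_TOP_P = (2, 3, 4, 5)


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classification function with its tuning grids.

    ``param_grid`` maps parameter names to candidate values in the order
    used for tie-breaking during tuning (earlier = preferred).
    """

    name: str
    param_grid: dict[str, tuple] = field(default_factory=dict)
    top_p_grid: tuple[int, ...] = NON_DISCRIMINANT_TOP_P

    def grid_points(self) -> list[dict[str, Any]]:
        """All parameter combinations, in documented tie-break order."""
        import itertools

        keys = list(self.param_grid)
        if not keys:
            return [{}]
        combos = itertools.product(*(self.param_grid[k] for k in keys))
        return [dict(zip(keys, c)) for c in combos]


def default_grids() -> dict[str, ClassifierSpec]:
    """The nine classifier specs with their full tuning grids."""
    return {
        "LDA": ClassifierSpec("LDA", {}, DISCRIMINANT_TOP_P),
        "DLDA": ClassifierSpec("DLDA", {}, DISCRIMINANT_TOP_P),
        "SCDA": ClassifierSpec("SCDA", {"lam": (0.1, 0.25, 0.5, 1, 2, 5)}),
        "RF": ClassifierSpec(
            "RF",
            {
                "n_trees": (500,),
                "m_mult": (0.1, 0.25, 0.5, 1, 2),
                "min_node": (1, 2, 3),
            },
        ),
        "TBB": ClassifierSpec("TBB", {"n_rounds": (50, 100, 200, 500, 1000)}),
        "RIDGE": ClassifierSpec(
            "RIDGE", {"lam": (0.0625, 0.125, 0.25, 0.5, 1, 2, 4, 8, 16)}
        ),
        "LASSO": ClassifierSpec(
            "LASSO", {"lam": (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)}
        ),
        "SVM": ClassifierSpec("SVM", {"C": (0.1, 1, 5, 10, 50, 100, 500)}),
        "KNN": ClassifierSpec("KNN", {"k": tuple(range(1, 11))}),
    }


def reduced_grids(n_trees: int = 100) -> dict[str, ClassifierSpec]:
    """Small grids for desk-scale runs: same methods, fewer candidates.

    Keeps two representative values per tuning parameter (one for the tree
    ensembles, whose fits dominate runtime) and two top-p counts, so the
    full nested protocol still exercises tuning at a fraction of the cost.
    """
    return {
        "LDA": ClassifierSpec("LDA", {}, (2, 3)),
        "DLDA": ClassifierSpec("DLDA", {}, (2, 3)),
        "SCDA": ClassifierSpec("SCDA", {"lam": (0.5, 2)}, (5, 25)),
        "RF": ClassifierSpec(
            "RF", {"n_trees": (n_trees,), "m_mult": (1,), "min_node": (1,)}, (10,)
        ),
        "TBB": ClassifierSpec("TBB", {"n_rounds": (50,)}, (10,)),
        "RIDGE": ClassifierSpec("RIDGE", {"lam": (0.25, 4)}, (5, 25)),
        "LASSO": ClassifierSpec("LASSO", {"lam": (0.1, 0.5)}, (5, 25)),
        "SVM": ClassifierSpec("SVM", {"C": (1, 100)}, (5, 25)),
        "KNN": ClassifierSpec("KNN", {"k": (1, 5)}, (5, 25)),
    }


def pointwise_grids(rf_trees: int = 40, tbb_rounds: int = 20) -> dict[str, ClassifierSpec]:
    """One representative grid point per method, for large simulation sweeps.

    With a single candidate the inner tuning loop is skipped entirely, so a
    multi-study suite can be benchmarked at a small fraction of the tuned
    cost while every method still runs the full outer resampling protocol.
    Ensemble sizes are scaled down accordingly.
    """
    return {
        "LDA": ClassifierSpec("LDA", {}, (3,)),
        "DLDA": ClassifierSpec("DLDA", {}, (3,)),
        "SCDA": ClassifierSpec("SCDA", {"lam": (1,)}, (10,)),
        "RF": ClassifierSpec(
            "RF", {"n_trees": (rf_trees,), "m_mult": (1,), "min_node": (1,)}, (10,)
        ),
        "TBB": ClassifierSpec("TBB", {"n_rounds": (tbb_rounds,)}, (10,)),
        "RIDGE": ClassifierSpec("RIDGE", {"lam": (1,)}, (10,)),
        "LASSO": ClassifierSpec("LASSO", {"lam": (0.2,)}, (10,)),
        "SVM": ClassifierSpec("SVM", {"C": (1,)}, (10,)),
        "KNN": ClassifierSpec("KNN", {"k": (3,)}, (10,)),
    }


# ----------------------------------------------------------------------
# fitted-model contract
# ----------------------------------------------------------------------


@dataclass
class FittedModel:
    """A trained predictor restricted to its selected probesets."""

    name: str
    params: dict[str, Any]
    probeset_ids: list[str]
    classes: np.ndarray  # sorted pair of labels
    _predictor: Any

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels for rows of ``X`` (samples x selected probesets)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.probeset_ids):
            raise ValueError(
                f"expected {len(self.probeset_ids)} features, got {X.shape[1]}"
            )
        idx = self._predictor.predict01(X)
        return self.classes[idx]

    def summary(self) -> dict:
        return {
            "method": self.name,
            "params": self.params,
            "probesets": list(self.probeset_ids),
        }


def predict_from_study(model: FittedModel, study) -> np.ndarray:
    """Predict every sample of a study, selecting the model's probesets."""
    missing = [p for p in model.probeset_ids if p not in set(study.probeset_ids)]
    if missing:
        raise KeyError(f"study lacks probesets required by the model: {missing}")
    sub = study.subset_probesets(model.probeset_ids)
    return model.predict(sub.matrix.T)


# ----------------------------------------------------------------------
# individual classifiers (binary, y coded 0/1 internally)
# ----------------------------------------------------------------------


class _LDA:
    """Gaussian classes with a shared full covariance matrix."""

    def fit(self, X, y01):
        n, p = X.shape
        if p >= n - 1:
            raise ValueError(
                f"LDA needs fewer probesets than samples (p={p}, n={n}); "
                "use a smaller top-p"
            )
        self.mu = np.stack([X[y01 == k].mean(axis=0) for k in (0, 1)])
        resid = np.vstack([X[y01 == k] - self.mu[k] for k in (0, 1)])
        cov = resid.T @ resid / (n - 2)
        try:
            cf = sla.cho_factor(cov)
        except np.linalg.LinAlgError as err:  # pragma: no cover - rare path
            raise ValueError(
                "singular pooled covariance; use a smaller top-p"
            ) from err
        except sla.LinAlgError as err:
            raise ValueError(
                "singular pooled covariance; use a smaller top-p"
            ) from err
        self.icov_mu = sla.cho_solve(cf, self.mu.T).T  # (2, p)
        self.cf = cf
        self.log_prior = np.log(np.bincount(y01, minlength=2) / n)
        return self

    def predict01(self, X):
        scores = X @ self.icov_mu.T - 0.5 * np.sum(self.mu * self.icov_mu, axis=1)
        scores = scores + self.log_prior
        # tie -> class 0 (lexicographically first label)
        return (scores[:, 1] > scores[:, 0]).astype(int)


class _DLDA:
    """Gaussian classes with a shared diagonal covariance."""

    def fit(self, X, y01):
        n = X.shape[0]
        self.mu = np.stack([X[y01 == k].mean(axis=0) for k in (0, 1)])
        resid = np.vstack([X[y01 == k] - self.mu[k] for k in (0, 1)])
        var = (resid**2).sum(axis=0) / (n - 2)
        if np.any(var <= 0):
            raise ValueError("zero within-class variance in a selected probeset")
        self.ivar = 1.0 / var
        self.log_prior = np.log(np.bincount(y01, minlength=2) / n)
        return self

    def predict01(self, X):
        scores = np.stack(
            [
                -0.5 * ((X - self.mu[k]) ** 2 * self.ivar).sum(axis=1)
                + self.log_prior[k]
                for k in (0, 1)
            ],
            axis=1,
        )
        return (scores[:, 1] > scores[:, 0]).astype(int)


class _SCDA:
    """Nearest shrunken centroids: standardized centroid deviations d_jk are
    soft-thresholded toward zero by lam before classification."""

    def __init__(self, lam):
        self.lam = float(lam)

    def fit(self, X, y01):
        n, p = X.shape
        nk = np.bincount(y01, minlength=2)
        overall = X.mean(axis=0)
        cent = np.stack([X[y01 == k].mean(axis=0) for k in (0, 1)])
        ss = sum(((X[y01 == k] - cent[k]) ** 2).sum(axis=0) for k in (0, 1))
        s = np.sqrt(ss / (n - 2))  # pooled within-class SD
        s0 = np.median(s)
        mk = np.sqrt(1.0 / nk - 1.0 / n)  # (2,)
        d = (cent - overall) / (mk[:, None] * (s + s0))
        d_shrunk = np.sign(d) * np.maximum(np.abs(d) - self.lam, 0.0)
        self.centroids = overall + mk[:, None] * (s + s0) * d_shrunk
        self.scale = s + s0
        self.log_prior = np.log(nk / n)
        return self

    def predict01(self, X):
        # discriminant score: standardized distance minus 2*log prior (argmin)
        delta = np.stack(
            [
                (((X - self.centroids[k]) / self.scale) ** 2).sum(axis=1)
                - 2.0 * self.log_prior[k]
                for k in (0, 1)
            ],
            axis=1,
        )
        # tie (equal scores, e.g. full shrinkage with balanced classes) -> class 0
        return (delta[:, 1] < delta[:, 0]).astype(int)


class _TBB:
    """Tree-based boosting: AdaBoost.M1 with weight-proportional resampling.

    Each round draws a with-replacement bootstrap of the learning samples
    using the current weights, grows a depth-2 classification tree on it,
    and up-weights the samples the tree misclassifies.  Resampling (rather
    than weight-aware tree fitting) keeps boosting productive even when a
    single tree separates the learning set perfectly: subsequent bootstrap
    draws still differ, so the ensemble keeps growing and averaging.
    """

    def __init__(self, n_rounds, seed):
        self.n_rounds = int(n_rounds)
        self.seed = seed

    def fit(self, X, y01):
        rng = np.random.default_rng(self.seed % (2**32))
        n = X.shape[0]
        w = np.full(n, 1.0 / n)
        self.trees = []
        self.alphas = []
        for t in range(self.n_rounds):
            idx = rng.choice(n, size=n, replace=True, p=w)
            tree = DecisionTreeClassifier(
                max_depth=2, random_state=int(rng.integers(2**31))
            ).fit(X[idx], y01[idx])
            pred = tree.predict(X)
            miss = pred != y01
            err = float(w[miss].sum())
            if err >= 0.5:
                # worse than chance on the weighted sample: reset and retry
                w = np.full(n, 1.0 / n)
                continue
            err_eff = max(err, 1.0 / (2.0 * n))  # floor keeps alpha finite at err=0
            alpha = math.log((1.0 - err_eff) / err_eff)
            self.trees.append(tree)
            self.alphas.append(alpha)
            if err > 0:
                w = w * np.exp(alpha * miss)
                w /= w.sum()
        if not self.trees:  # pragma: no cover - requires adversarial input
            raise ValueError("boosting produced no usable tree")
        return self

    def predict01(self, X):
        score = np.zeros(X.shape[0])
        for tree, alpha in zip(self.trees, self.alphas):
            score += alpha * (2.0 * tree.predict(X) - 1.0)
        return (score > 0).astype(int)


class _SklearnWrap:
    def __init__(self, est, standardize=False):
        self.est = est
        self.standardize = standardize

    def fit(self, X, y01):
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1)
            self.sd_ = np.where(sd > 0, sd, 1.0)
            X = (X - self.mean_) / self.sd_
        self.est.fit(X, y01)
        return self

    def predict01(self, X):
        if self.standardize:
            X = (X - self.mean_) / self.sd_
        return self.est.predict(X).astype(int)


class _KNN:
    """Deterministic K nearest neighbours (Euclidean).

    Neighbours are ordered by (distance, learning-sample index); a vote tie
    is resolved to the nearest neighbour's class.
    """

    def __init__(self, k):
        self.k = int(k)

    def fit(self, X, y01):
        self.X = X
        self.y = y01
        return self

    def predict01(self, X):
        d = np.sqrt(((X[:, None, :] - self.X[None, :, :]) ** 2).sum(axis=2))
        out = np.empty(X.shape[0], dtype=int)
        idx = np.arange(self.X.shape[0])
        for i in range(X.shape[0]):
            order = np.lexsort((idx, d[i]))[: self.k]
            votes = np.bincount(self.y[order], minlength=2)
            if votes[0] == votes[1]:
                out[i] = self.y[order[0]]
            else:
                out[i] = int(votes[1] > votes[0])
        return out


def _build(name: str, params: dict, n_samples: int, seed: int):
    if name == "LDA":
        return _LDA()
    if name == "DLDA":
        return _DLDA()
    if name == "SCDA":
        return _SCDA(params["lam"])
    if name == "RF":
        return _SklearnWrap(
            RandomForestClassifier(
                n_estimators=int(params.get("n_trees", 500)),
                max_features=None,  # set at fit time below
                min_samples_leaf=int(params["min_node"]),
                bootstrap=True,
                max_samples=math.ceil(2 * n_samples / 3),
                random_state=seed % (2**32),
                n_jobs=1,
            )
        )
    if name == "TBB":
        return _TBB(params["n_rounds"], seed)
    if name == "RIDGE":
        return _SklearnWrap(
            LogisticRegression(
                l1_ratio=0.0, C=1.0 / params["lam"], solver="lbfgs", max_iter=10000
            ),
            standardize=True,
        )
    if name == "LASSO":
        # liblinear: fast L1 coordinate descent; the large intercept_scaling
        # keeps the intercept effectively unpenalized
        return _SklearnWrap(
            LogisticRegression(
                l1_ratio=1.0, C=1.0 / params["lam"], solver="liblinear",
                intercept_scaling=100.0, max_iter=5000,
            ),
            standardize=True,
        )
    if name == "SVM":
        return _SklearnWrap(SVC(kernel="linear", C=params["C"]), standardize=True)
    if name == "KNN":
        return _KNN(params["k"])
    raise ValueError(f"unknown classifier {name!r}")


def fit(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    params: dict[str, Any],
    probeset_ids: list[str] | None = None,
    seed: int = 0,
) -> FittedModel:
    """Train one classifier at one grid point.

    ``X`` is (samples x features), already restricted to the chosen
    top-ranked probesets; ``y`` holds the two class labels.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes in y, got {classes.tolist()}")
    y01 = (y == classes[1]).astype(int)
    n, p = X.shape
    if probeset_ids is None:
        probeset_ids = [f"f{j}" for j in range(p)]
    predictor = _build(spec.name, params, n, seed)
    if spec.name == "RF":
        m = min(p, max(1, round(params["m_mult"] * math.sqrt(p))))
        predictor.est.set_params(max_features=m)
    predictor.fit(X, y01)
    return FittedModel(
        name=spec.name,
        params=dict(params),
        probeset_ids=list(probeset_ids),
        classes=classes,
        _predictor=predictor,
    )
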