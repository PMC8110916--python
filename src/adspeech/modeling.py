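"""Feature selection, classifier and regressor configurations.

Models are scikit-learn pipelines: a top-k univariate filter (ANOVA F for
classification, squared-correlation F for MMSE regression), z-scoring with
training-partition statistics for the margin/gradient models (SVM, neural
network, linear/ridge regression), and a predictor with the tuned
hyperparameters reported for this battery:

* ``svm_rbf`` — RBF kernel, gamma = 0.001, C = 100 (k = 10 features)
* ``nn``      — 2 hidden layers x 10 ReLU units, Adam, 200 epochs,
                full-batch (k = 10)
* ``rf``      — 200 trees, min-split 2, min-leaf 2, bootstrap (k = 50)
* ``nb``      — Gaussian, balanced priors, variance smoothing 1e-10 (k = 80)
* ``linreg`` / ``ridge`` — least squares / L2, correlation-F selection,
                predictions clipped to [0, 30] (ridge: k = 25, alpha = 10)

Selection ties are broken by ascending feature index, so fits are
deterministic; only ``rf`` and ``nn`` consume the random seed.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

ModelFamily = Literal["svm_rbf", "nn", "rf", "nb", "linreg", "ridge"]

CLASSIFIER_FAMILIES = ("svm_rbf", "nn", "rf", "nb")
REGRESSOR_FAMILIES = ("linreg", "ridge")

#: reported tuned feature counts per classifier family
DEFAULT_K = {"svm_rbf": 10, "nn": 10, "rf": 50, "nb": 80,
             "ridge": 25, "linreg": 20}

MMSE_MIN, MMSE_MAX = 0.0, 30.0


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    family: ModelFamily
    k: int = 0                      # 0 -> family default
    seed: int = 1
    alpha: float = 10.0             # ridge penalty
    hyperparameters: dict = dataclasses.field(default_factory=dict)

    def resolved_k(self, n_features: int | None = None) -> int:
        k = self.k or DEFAULT_K[self.family]
        if n_features is not None:
            k = min(k, n_features)
        if k < 1:
            raise ValueError("k must be >= 1")
        return k


# ---------------------------------------------------------------------------
# univariate scores and the top-k transformer
# ---------------------------------------------------------------------------

def anova_f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature one-way ANOVA F between the two class-conditional
    distributions; zero-variance features score 0."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    n = len(y)
    groups = [X[y], X[~y]]
    grand = X.mean(axis=0)
    ss_between = sum(len(g) * (g.mean(axis=0) - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
    df_between, df_within = 1, n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_between) / (ss_within / df_within)
    # constant features (no between- or within-group variation) score 0;
    # perfect separators (within-group variance 0, means differ) rank top
    f = np.where(ss_within > 0, f,
                 np.where(ss_between > 0, np.finfo(float).max, 0.0))
    f[np.isnan(f)] = 0.0
    return f


def mmse_corr_f_scores(X: np.ndarray, mmse: np.ndarray) -> np.ndarray:
    """F statistics from the squared Pearson correlation of each feature
    with the MMSE score; constant features score 0."""
    X = np.asarray(X, dtype=float)
    t = np.asarray(mmse, dtype=float)
    n = len(t)
    xc = X - X.mean(axis=0)
    tc = t - t.mean()
    denom = np.sqrt((xc ** 2).sum(axis=0) * (tc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * tc[:, None]).sum(axis=0) / denom
        r2 = np.clip(r ** 2, 0.0, 1.0)
        f = r2 / (1.0 - r2) * (n - 2)
    f[~np.isfinite(r)] = 0.0
    f[np.isinf(f)] = np.finfo(float).max
    return f


def top_k_indices(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores; ties broken by ascending index."""
    if k > len(scores):
        raise ValueError(f"k={k} exceeds feature count {len(scores)}")
    order = np.argsort(-np.asarray(scores), kind="stable")
    return np.sort(order[:k])


def select_top_k_anova(X, y, k) -> np.ndarray:
    return top_k_indices(anova_f_scores(X, y), k)


def select_top_k_mmse_corr(X, mmse, k) -> np.ndarray:
    return top_k_indices(mmse_corr_f_scores(X, mmse), k)


class TopKSelector(BaseEstimator, TransformerMixin):
    """sklearn transformer wrapping the deterministic top-k filter."""

    def __init__(self, k: int = 10, score: str = "anova"):
        self.k = k
        self.score = score

    def fit(self, X, y):
        scorer = anova_f_scores if self.score == "anova" else mmse_corr_f_scores
        self.scores_ = scorer(np.asarray(X, dtype=float), np.asarray(y))
        self.indices_ = top_k_indices(self.scores_, self.k)
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.indices_]


# ---------------------------------------------------------------------------
# fitted models
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FittedModel:
    spec: ModelSpec
    pipeline: Pipeline

    @property
    def selected_indices(self) -> np.ndarray:
        return self.pipeline.named_steps["select"].indices_

    def predict(self, X) -> np.ndarray:
        return self.pipeline.predict(np.asarray(X, dtype=float))

    def decision_scores(self, X) -> np.ndarray:
        """Continuous scores for ranking (AUROC); larger -> positive class."""
        X = np.asarray(X, dtype=float)
        est = self.pipeline
        if hasattr(est.named_steps["model"], "decision_function"):
            return est.decision_function(X)
        if hasattr(est.named_steps["model"], "predict_proba"):
            return est.predict_proba(X)[:, 1]
        return est.predict(X).astype(float)


def _make_classifier(spec: ModelSpec, n_train: int):
    hp = spec.hyperparameters
    if spec.family == "svm_rbf":
        return SVC(kernel="rbf", gamma=hp.get("gamma", 0.001),
                   C=hp.get("C", 100.0)), True
    if spec.family == "nn":
        return MLPClassifier(
            hidden_layer_sizes=hp.get("layers", (10, 10)),
            activation="relu", solver="adam",
            learning_rate_init=hp.get("learning_rate", 1e-3),
            max_iter=hp.get("epochs", 200), batch_size=max(2, n_train),
            random_state=spec.seed), True
    if spec.family == "rf":
        return RandomForestClassifier(
            n_estimators=hp.get("trees", 200), min_samples_split=2,
            min_samples_leaf=2, bootstrap=True,
            random_state=spec.seed), False
    if spec.family == "nb":
        return GaussianNB(priors=[0.5, 0.5],
                          var_smoothing=hp.get("var_smoothing", 1e-10)), False
    raise ValueError(f"unknown classifier family {spec.family}")


def fit_classifier(spec: ModelSpec, X, y) -> FittedModel:
    """Fit top-k ANOVA selection + the configured classifier.

    SVM and NN features are z-scored with training statistics; RF and NB
    take raw selected features.  Raises on single-class ``y``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    if y.all() or not y.any():
        raise ValueError("training labels contain a single class")
    k = spec.resolved_k(X.shape[1])
    model, scale = _make_classifier(spec, len(y))
    steps = [("select", TopKSelector(k=k, score="anova"))]
    if scale:
        steps.append(("scale", StandardScaler()))
    steps.append(("model", model))
    pipe = Pipeline(steps)
    import warnings
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        warnings.filterwarnings(
            "ignore", message=".*Maximum iterations.*")
        from sklearn.exceptions import ConvergenceWarning
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        pipe.fit(X, y)
    return FittedModel(spec=spec, pipeline=pipe)


def fit_regressor(spec: ModelSpec, X, mmse) -> FittedModel:
    """Fit correlation-F top-k selection + standardized linear/ridge."""
    X = np.asarray(X, dtype=float)
    t = np.asarray(mmse, dtype=float)
    if spec.family not in REGRESSOR_FAMILIES:
        raise ValueError(f"not a regressor family: {spec.family}")
    k = spec.resolved_k()
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {X.shape[1]}")
    model = (Ridge(alpha=spec.alpha) if spec.family == "ridge"
             else LinearRegression())
    pipe = Pipeline([
        ("select", TopKSelector(k=k, score="mmse_corr")),
        ("scale", StandardScaler()),
        ("model", model),
    ])
    pipe.fit(X, t)
    return FittedModel(spec=spec, pipeline=pipe)


def predict_mmse(model: FittedModel, X) -> np.ndarray:
    """Regression predictions clipped into the MMSE range [0, 30]."""
    return np.clip(model.predict(X), MMSE_MIN, MMSE_MAX)


def regression_coefficients(model: FittedModel,
                            n_features: int) -> np.ndarray:
    """Coefficients mapped back to the full feature space (0 where a
    feature was not selected); on the standardized-feature scale."""
    coefs = np.zeros(n_features)
    est = model.pipeline.named_steps["model"]
    coefs[model.selected_indices] = est.coef_
    return coefs
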