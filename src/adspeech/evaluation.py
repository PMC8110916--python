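"""Evaluation protocol: LOSO and stratified 10-fold CV, three-seed
averaging, majority-vote test predictions, classification/regression
metrics and the Kruskal-Wallis model comparison.

Selection, scaling and model fitting are all refit inside every training
fold, so no held-out subject influences any fitted component of the fold
that tests it.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .features import CohortTable
from .modeling import (FittedModel, ModelSpec, fit_classifier, fit_regressor,
                       predict_mmse)

DEFAULT_SEEDS = (1, 2, 3)

CLASSIFICATION_METRICS = ("accuracy", "precision", "recall", "specificity",
                          "f1", "auroc")


@dataclasses.dataclass(frozen=True)
class CVPlan:
    """Fold assignments per subject (subjects partitioned across folds)."""

    scheme: str                        # "loso" | "kfold"
    folds: tuple[tuple[str, ...], ...]  # test subjects per fold
    seed: int = 0

    def __post_init__(self):
        flat = [s for fold in self.folds for s in fold]
        if len(flat) != len(set(flat)):
            raise ValueError("folds must not overlap")

    @property
    def subjects(self) -> set[str]:
        return {s for fold in self.folds for s in fold}


def make_loso_plan(subject_ids: list[str]) -> CVPlan:
    """One fold per subject."""
    return CVPlan(scheme="loso", folds=tuple((s,) for s in subject_ids))


def make_kfold_plan(subject_ids: list[str], labels: np.ndarray, k: int = 10,
                    seed: int = 0) -> CVPlan:
    """Stratified k-fold over subjects (the dataset design is balanced).

    With k equal to the subject count the plan degenerates to
    leave-one-subject-out (stratification is vacuous for singleton folds).
    """
    ids = np.asarray(subject_ids)
    if k == len(ids):
        return CVPlan(scheme="kfold", folds=tuple((s,) for s in ids),
                      seed=seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = tuple(tuple(ids[test]) for _, test in
                  skf.split(ids, np.asarray(labels).astype(int)))
    return CVPlan(scheme="kfold", folds=folds, seed=seed)


def classification_metrics(y_true, y_pred, scores=None) -> dict[str, float]:
    """Accuracy, precision, recall, specificity, F1 (positive class = AD)
    and rank-statistic AUROC.  Metrics undefined on single-class inputs are
    reported as NaN."""
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    tp = int((y_true & y_pred).sum())
    tn = int((~y_true & ~y_pred).sum())
    fp = int((~y_true & y_pred).sum())
    fn = int((y_true & ~y_pred).sum())
    out = {
        "accuracy": (tp + tn) / len(y_true),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }
    p, r = out["precision"], out["recall"]
    out["f1"] = (2 * p * r / (p + r)
                 if np.isfinite(p) and np.isfinite(r) and p + r > 0
                 else float("nan"))
    if scores is None:
        scores = y_pred.astype(float)
    scores = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y_true.sum()), int((~y_true).sum())
    if n_pos and n_neg:
        ranks = stats.rankdata(scores)
        out["auroc"] = (ranks[y_true].sum()
                        - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    else:
        out["auroc"] = float("nan")
    return out


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    err = y_pred - y_true
    return {"rmse": float(np.sqrt(np.mean(err ** 2))),
            "mae": float(np.mean(np.abs(err)))}


@dataclasses.dataclass
class EvalReport:
    per_seed: dict[int, dict[str, float]]
    mean: dict[str, float]
    predictions: dict[int, dict[str, float]]  # seed -> subject -> prediction

    @property
    def seeds(self) -> list[int]:
        return sorted(self.per_seed)


def _fold_arrays(cohort: CohortTable, plan: CVPlan):
    ids = np.asarray(cohort.subject_ids)
    pos = {s: i for i, s in enumerate(ids)}
    for fold in plan.folds:
        test_idx = np.array([pos[s] for s in fold])
        train_mask = np.ones(len(ids), dtype=bool)
        train_mask[test_idx] = False
        yield np.where(train_mask)[0], test_idx


def run_cv(plan: CVPlan, spec: ModelSpec, cohort: CohortTable,
           seeds=DEFAULT_SEEDS, task: str = "classify") -> EvalReport:
    """Per seed: fit (selection + scaling + model) on each training fold,
    predict its held-out subjects, pool the predictions over folds, and
    compute metrics; then average metrics over seeds."""
    if plan.subjects != set(cohort.subject_ids):
        raise ValueError("plan subjects do not match cohort")
    X = cohort.X
    target = cohort.y if task == "classify" else cohort.mmse
    ids = np.asarray(cohort.subject_ids)

    per_seed: dict[int, dict[str, float]] = {}
    predictions: dict[int, dict[str, float]] = {}
    for seed in seeds:
        sspec = dataclasses.replace(spec, seed=seed)
        pred = np.empty(len(ids), dtype=float)
        score = np.empty(len(ids), dtype=float)
        for train_idx, test_idx in _fold_arrays(cohort, plan):
            if task == "classify":
                model = fit_classifier(sspec, X[train_idx], target[train_idx])
                pred[test_idx] = model.predict(X[test_idx]).astype(float)
                score[test_idx] = model.decision_scores(X[test_idx])
            else:
                model = fit_regressor(sspec, X[train_idx], target[train_idx])
                pred[test_idx] = predict_mmse(model, X[test_idx])
        if task == "classify":
            per_seed[seed] = classification_metrics(
                target.astype(bool), pred.astype(bool), score)
        else:
            per_seed[seed] = regression_metrics(target, pred)
        predictions[seed] = dict(zip(ids.tolist(), pred.tolist()))

    keys = next(iter(per_seed.values())).keys()
    mean = {k: float(np.mean([per_seed[s][k] for s in per_seed]))
            for k in keys}
    return EvalReport(per_seed=per_seed, mean=mean, predictions=predictions)


def majority_vote_predict(models: list[FittedModel], X_test) -> np.ndarray:
    """Modal label over an odd number of fitted voters."""
    if len(models) % 2 == 0:
        raise ValueError("majority vote requires an odd number of voters")
    votes = np.stack([m.predict(X_test).astype(int) for m in models])
    return np.array([Counter(col).most_common(1)[0][0]
                     for col in votes.T]).astype(bool)


def train_and_vote(spec: ModelSpec, cohort_train: CohortTable, X_test,
                   seeds=DEFAULT_SEEDS) -> np.ndarray:
    """The held-out-test protocol: train on the full training cohort with
    each seed and majority-vote the three predictions."""
    models = [fit_classifier(dataclasses.replace(spec, seed=s),
                             cohort_train.X, cohort_train.y) for s in seeds]
    return majority_vote_predict(models, X_test)


def compare_models_kw(per_run_accuracies: dict[str, list[float]]
                      ) -> dict[str, float]:
    """Kruskal-Wallis H (tie-corrected) over per-run accuracy lists.

    Identical values across all groups yield H = 0 rather than the
    undefined tie-corrected statistic.
    """
    groups = list(per_run_accuracies.values())
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return {"H": 0.0, "p": 1.0}
    h, p = stats.kruskal(*groups)
    return {"H": float(h), "p": float(p)}
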