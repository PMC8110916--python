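"""Feature-differentiation analysis and MMSE regression-weight reporting.

Differentiation: per-feature Welch two-sample t-tests between the AD and
non-AD group means, flagged at the nominal level and after Bonferroni
correction (alpha / m with m = number of features tested; the threshold
actually used is recorded in the report).

Weight report: a leave-one-subject-out ridge regression of MMSE on the
battery; each feature's coefficient (on standardized features) is averaged
across folds, with 0 contributed in folds where the feature was not
selected, and paired with its Pearson correlation with MMSE.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import make_loso_plan
from .features import CohortTable
from .modeling import (ModelSpec, fit_regressor, regression_coefficients)


@dataclasses.dataclass
class DifferentiationReport:
    table: pd.DataFrame         # per feature: mean_ad, mean_non_ad, t, p, flags
    alpha: float
    bonferroni_threshold: float
    n_significant_raw: int
    n_significant_bonferroni: int


def differentiate_features(cohort: CohortTable,
                           alpha: float = 0.05) -> DifferentiationReport:
    """Welch t-test per feature between groups; zero-variance-in-both-groups
    features get t = 0, p = 1 by convention."""
    y = cohort.y
    if y.all() or not y.any():
        raise ValueError("both groups must be non-empty")
    X = cohort.X
    a, b = X[y], X[~y]
    m = X.shape[1]
    import warnings
    with np.errstate(divide="ignore", invalid="ignore"), \
            warnings.catch_warnings():
        # near-constant features trigger scipy precision warnings; they are
        # handled by the degenerate-case convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=False, axis=0)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    threshold = alpha / m
    table = pd.DataFrame({
        "mean_ad": a.mean(axis=0),
        "mean_non_ad": b.mean(axis=0),
        "t": t,
        "p": p,
        "significant_raw": p < alpha,
        "significant_bonferroni": p < threshold,
    }, index=cohort.features.columns)
    return DifferentiationReport(
        table=table, alpha=alpha, bonferroni_threshold=threshold,
        n_significant_raw=int(table["significant_raw"].sum()),
        n_significant_bonferroni=int(table["significant_bonferroni"].sum()),
    )


@dataclasses.dataclass
class WeightReport:
    table: pd.DataFrame     # per feature: mean_weight, correlation, corr_p,
    #                         significant (Bonferroni), sign_concordant
    top5: pd.DataFrame
    bottom5: pd.DataFrame
    alpha: float


def weight_report(cohort: CohortTable,
                  spec: ModelSpec | None = None,
                  alpha: float = 0.05) -> WeightReport:
    """LOSO ridge-regression weights averaged across folds, with Pearson
    MMSE correlations and Bonferroni significance flags."""
    spec = spec or ModelSpec(family="ridge", k=25, alpha=10.0)
    mmse = cohort.mmse
    if np.isnan(mmse).any():
        raise ValueError("MMSE must be present for all rows")
    X = cohort.X
    n, m = X.shape
    plan = make_loso_plan(cohort.subject_ids)
    weights = np.zeros(m)
    for fold in plan.folds:
        test = {fold[0]}
        mask = np.array([s not in test for s in cohort.subject_ids])
        model = fit_regressor(spec, X[mask], mmse[mask])
        weights += regression_coefficients(model, m)
    weights /= len(plan.folds)

    corr = np.zeros(m)
    corr_p = np.ones(m)
    for j in range(m):
        col = X[:, j]
        if np.std(col) == 0:
            continue
        r, pv = stats.pearsonr(col, mmse)
        corr[j], corr_p[j] = r, pv
    threshold = alpha / m
    table = pd.DataFrame({
        "mean_weight": weights,
        "correlation": corr,
        "corr_p": corr_p,
        "significant": corr_p < threshold,
        "sign_concordant": np.sign(weights) == np.sign(corr),
    }, index=cohort.features.columns)
    nonzero = table[table["mean_weight"] != 0].sort_values(
        "mean_weight", ascending=False)
    k = min(5, len(nonzero))
    return WeightReport(table=table.reindex(
        table["mean_weight"].abs().sort_values(ascending=False).index),
        top5=nonzero.head(k), bottom5=nonzero.tail(k).iloc[::-1],
        alpha=alpha)
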