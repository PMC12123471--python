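"""Base risk-model learners and hyperparameter tuning.

The pipeline treats the admission classifier as a pluggable component:
penalized logistic regression (penalty l1/l2, C grid 0.01-10), a random
forest (100 estimators, depth 4), or an XGBoost ensemble with the same
budget.  Protected attributes enter the design matrix as one-hot main
effects only — deliberately, so interaction-driven subgroup structure in the
data is not representable by the logistic learner and must be addressed by
the fairness machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.experimental import enable_halving_search_cv  # noqa: F401
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import HalvingGridSearchCV, StratifiedKFold

__all__ = ["LearnerSpec", "design_matrix", "make_estimator", "tune_learner"]

# l1_ratio 1.0 is the lasso penalty, 0.0 the ridge penalty
LOGISTIC_GRID = {"l1_ratio": [1.0, 0.0], "C": [0.01, 0.1, 1.0, 10.0]}


@dataclass(frozen=True)
class LearnerSpec:
    """What to fit and on which columns.

    model: 'logistic' | 'tree' | 'xgboost'; ``grid`` overrides the default
    hyperparameter grid (a single-point grid skips the search);
    ``include_protected`` controls whether protected one-hots are features.
    """

    model: str = "logistic"
    feature_columns: tuple = ()
    protected: tuple = ()
    grid: dict | None = None
    include_protected: bool = True
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in ("logistic", "tree", "xgboost"):
            raise ValueError(f"unknown model {self.model!r}")


def design_matrix(spec: LearnerSpec, frame: pd.DataFrame) -> np.ndarray:
    """Numeric features plus one-hot protected attributes (main effects).

    Protected columns must be pandas Categorical so train and test expand
    to the same dummy columns.
    """
    parts = [frame[list(spec.feature_columns)].to_numpy(dtype=float)]
    if spec.include_protected and spec.protected:
        dummies = pd.get_dummies(frame[list(spec.protected)])
        parts.append(dummies.to_numpy(dtype=float))
    return np.hstack(parts)


def make_estimator(spec: LearnerSpec, seed: int = 0, **overrides):
    params = {**spec.params, **overrides}
    if spec.model == "logistic":
        l1_ratio = params.get("l1_ratio")
        if l1_ratio is None:  # accept the classical penalty spelling too
            l1_ratio = 1.0 if params.get("penalty", "l2") == "l1" else 0.0
        return LogisticRegression(
            l1_ratio=l1_ratio, C=params.get("C", 1.0),
            solver="liblinear", max_iter=1000, random_state=seed)
    if spec.model == "tree":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 100),
            max_depth=params.get("max_depth", 4),
            random_state=seed, n_jobs=1)
    from xgboost import XGBClassifier

    return XGBClassifier(
        n_estimators=params.get("n_estimators", 100),
        max_depth=params.get("max_depth", 4),
        random_state=seed, n_jobs=1, verbosity=0)


def tune_learner(spec: LearnerSpec, X: np.ndarray, y: np.ndarray,
                 seed: int = 0, sample_weight=None):
    """Successive-halving grid search, 3-fold stratified CV, balanced
    accuracy; returns a fitted estimator.  A missing or single-point grid
    fits directly without searching.
    """
    grid = spec.grid if spec.grid is not None else (
        LOGISTIC_GRID if spec.model == "logistic" else {})
    n_points = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    fit_kw = {} if sample_weight is None else {"sample_weight": sample_weight}
    if n_points <= 1:
        single = {k: v[0] for k, v in grid.items()} if grid else {}
        est = make_estimator(spec, seed, **single)
        est.fit(X, y, **fit_kw)
        return est
    search = HalvingGridSearchCV(
        make_estimator(spec, seed), grid,
        cv=StratifiedKFold(3, shuffle=True, random_state=seed),
        scoring="balanced_accuracy", factor=2, random_state=seed)
    search.fit(X, y, **fit_kw)
    return search.best_estimator_


def predict_risk(estimator, X: np.ndarray) -> np.ndarray:
    return estimator.predict_proba(X)[:, 1]
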