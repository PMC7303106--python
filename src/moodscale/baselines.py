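"""Comparison models: naive means, ridge regression and boosted trees.

Each comes in a *pooled* variant (one model for everybody) and a
*separate* variant (one model per training subject).  All variants consume
exactly the same engineered feature matrix as the Bayesian models.

Separate variants fall back to the pooled training statistic for subjects
absent from training (cold start), and a separate regression for a subject
with fewer rows than features falls back to that subject's mean (the fit
would be ill posed otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import Ridge
from xgboost import XGBRegressor

from .preprocess import ModelDataset

logger = logging.getLogger(__name__)

KINDS = (
    "pooled_mean",
    "separate_mean",
    "pooled_l2",
    "separate_l2",
    "pooled_gbt",
    "separate_gbt",
)


@dataclass
class BaselineModel:
    """One baseline with its hyperparameters and (after ``fit``) its state.

    Hyperparameters are not tuned; the defaults are fixed once and recorded
    with every results file.
    """

    kind: str
    l2_penalty: float = 1.0
    n_rounds: int = 100
    max_depth: int = 3
    learning_rate: float = 0.1
    seed: int = 0

    global_mean_: float | None = field(default=None, repr=False)
    subject_means_: dict[str, float] | None = field(default=None, repr=False)
    estimator_: object | None = field(default=None, repr=False)
    subject_estimators_: dict[str, object] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}; expected one of {KINDS}")

    @property
    def is_fitted(self) -> bool:
        return self.global_mean_ is not None

    def hyperparameters(self) -> dict:
        if self.kind.endswith("_l2"):
            return {"l2_penalty": self.l2_penalty}
        if self.kind.endswith("_gbt"):
            return {
                "n_rounds": self.n_rounds,
                "max_depth": self.max_depth,
                "learning_rate": self.learning_rate,
                "seed": self.seed,
            }
        return {}


def _make_regressor(model: BaselineModel):
    if model.kind.endswith("_l2"):
        return Ridge(alpha=model.l2_penalty)
    return XGBRegressor(
        n_estimators=model.n_rounds,
        max_depth=model.max_depth,
        learning_rate=model.learning_rate,
        random_state=model.seed,
        verbosity=0,
        n_jobs=1,
    )


def fit(model: BaselineModel, dataset: ModelDataset) -> BaselineModel:
    """Fit on a model dataset; returns a fitted copy."""
    X, y, subj_idx = dataset.design()
    if len(y) == 0:
        raise ValueError("cannot fit a baseline on an empty dataset")
    subjects = dataset.subjects
    fitted = replace(model)
    fitted.global_mean_ = float(np.mean(y))
    by_subject = {
        s: np.flatnonzero(subj_idx == j) for j, s in enumerate(subjects)
    }
    empty = [s for s, rows in by_subject.items() if len(rows) == 0]
    if model.kind.startswith("separate") and empty:
        raise ValueError(f"separate baseline requires rows for every subject; none for {empty}")
    fitted.subject_means_ = {s: float(np.mean(y[rows])) for s, rows in by_subject.items()}

    if model.kind in ("pooled_l2", "pooled_gbt"):
        est = _make_regressor(model)
        est.fit(X, y)
        fitted.estimator_ = est
    elif model.kind in ("separate_l2", "separate_gbt"):
        fitted.subject_estimators_ = {}
        for s, rows in by_subject.items():
            if model.kind == "separate_l2" and len(rows) <= X.shape[1]:
                # ill-posed: fewer rows than coefficients -> subject mean
                continue
            est = _make_regressor(model)
            est.fit(X[rows], y[rows])
            fitted.subject_estimators_[s] = est
    return fitted


def predict(model: BaselineModel, X: np.ndarray, subject_ids) -> np.ndarray:
    """Predict for rows with the given subjects; deterministic given the fit."""
    if not model.is_fitted:
        raise ValueError("baseline model is not fitted")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    subject_ids = list(subject_ids)

    if model.kind == "pooled_mean":
        return np.full(n, model.global_mean_)
    if model.kind in ("pooled_l2", "pooled_gbt"):
        return np.asarray(model.estimator_.predict(X), dtype=float)

    out = np.empty(n)
    unseen = sorted({s for s in subject_ids if s not in model.subject_means_})
    if unseen:
        logger.info("unseen subjects %s served by the pooled training mean", unseen)
    for i, sid in enumerate(subject_ids):
        if sid not in model.subject_means_:
            out[i] = model.global_mean_
        elif model.kind == "separate_mean" or (
            model.subject_estimators_ is not None and sid not in model.subject_estimators_
        ):
            out[i] = model.subject_means_[sid]
        else:
            out[i] = float(model.subject_estimators_[sid].predict(X[i : i + 1])[0])
    return out
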