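"""Daily relapse-risk scores from posterior predictive uncertainty.

The risk that a subject is experiencing a clinically severe state on a
given day is the posterior predictive exceedance probability
Pr(y~ >= T) with T = 13 on the total-score scales (a total of 13 or more
classifies a depressive or manic episode; item-1 models are excluded from
risk scoring because the threshold is a total-score criterion).

Treating days with a true rating >= T as the positive class, the scores
are evaluated as a binary classifier via ROC curves and AUC.  Mean-model
baselines produce degenerate binary scores (a pooled mean below T marks
everyone low-risk), so their step-like ROC curves and chance-level AUC are
expected behaviour, not a bug.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from . import baselines as bl

DEFAULT_THRESHOLD = 13.0
RISK_TARGETS = ("hdrs_total", "ymrs_total")


def exceedance_probability(draws: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Fraction of predictive draws >= threshold, per row, with its MC error.

    ``draws`` has shape (n_draws, n_rows) with at least 100 draws per row.
    Returns columns ``probability``, ``mc_se`` and ``n_draws``.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] == 0:
        raise ValueError("draws must be a nonempty (n_draws, n_rows) array")
    n = draws.shape[0]
    if n < 100:
        raise ValueError(f"need at least 100 draws per row for a stable estimate; got {n}")
    p = np.mean(draws >= threshold, axis=0)
    return pd.DataFrame(
        {
            "probability": p,
            "mc_se": np.sqrt(p * (1.0 - p) / n),
            "n_draws": n,
        }
    )


def risk_scores(
    draws: np.ndarray,
    rows: pd.DataFrame,
    target_name: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Per-day risk table (subject, date, target, threshold, probability)."""
    if target_name not in RISK_TARGETS:
        raise ValueError(
            f"risk scoring is defined for total scores only ({RISK_TARGETS}); got {target_name!r}"
        )
    ex = exceedance_probability(draws, threshold)
    out = rows[["subject_id", "date"]].reset_index(drop=True).copy()
    out["target"] = target_name
    out["threshold"] = threshold
    out["probability"] = ex["probability"]
    out["mc_se"] = ex["mc_se"]
    out["n_draws"] = ex["n_draws"]
    return out


def baseline_risk(
    model: bl.BaselineModel,
    X: np.ndarray,
    subject_ids,
    threshold: float = DEFAULT_THRESHOLD,
) -> np.ndarray:
    """Binary risk 1{y_hat >= T} from a fitted baseline.

    A pooled mean model yields a constant score (all low or all high risk);
    a separate mean model a per-subject constant.
    """
    y_hat = bl.predict(model, X, subject_ids)
    return (y_hat >= threshold).astype(float)


@dataclass
class RocResult:
    """ROC points and trapezoid AUC; positive class is y >= T."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Threshold-sweep ROC with trapezoid AUC.

    Ties in the scores are handled by the rank-based construction, making
    the AUC equal to the Mann-Whitney U statistic divided by n_pos * n_neg.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"labels must contain both classes (0 and 1); got {classes.tolist()}")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=float(_trapezoid_auc(fpr, tpr)))
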