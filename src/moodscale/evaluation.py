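"""Cross-validation, metrics, model comparison and variable importance.

The cross-validation design holds out one randomly chosen clinical
evaluation per subject in each of K iterations; the held-out visit's whole
validity window (up to 4 day-level rows) moves together, and the
per-subject sleep means are recomputed on the training rows of each fold
so no held-out information leaks into the features.

Predicted R^2 uses the held-out set's own mean in the denominator
(1 - SSE / SS_test), so a pooled training-mean predictor scores about zero
and models worse than the mean score negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import baselines as bl
from . import hier
from .preprocess import ModelDataset, refit_sleep_features

logger = logging.getLogger(__name__)

BAYESIAN_MODELS = ("hierarchical", "pooled_bayesian")
ALL_MODELS = BAYESIAN_MODELS + bl.KINDS


# ---------------------------------------------------------------------------
# metrics


def predicted_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """1 - SSE / sum((y - mean(y_test))^2); NaN if the held-out y is constant."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, nonempty")
    denom = float(np.sum((y_true - y_true.mean()) ** 2))
    if denom == 0.0:
        return float("nan")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / denom


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, nonempty")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


# ---------------------------------------------------------------------------
# CV plan


@dataclass
class CVPlan:
    """K iterations of one held-out visit (rating date) per subject."""

    K: int
    seed: int
    assignments: list[dict[str, pd.Timestamp]]

    def __post_init__(self) -> None:
        if len(self.assignments) != self.K:
            raise ValueError("assignments must have one entry per iteration")


def make_cv_plan(dataset: ModelDataset, K: int, seed: int) -> CVPlan:
    """Uniformly sample one held-out visit per subject per iteration.

    Requires every subject to have at least three distinct visits in the
    dataset, so each training fold retains at least two visits per subject.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    visits = {
        s: sorted(g["rating_date"].unique())
        for s, g in dataset.frame.groupby("subject_id")
    }
    too_few = sorted(s for s, v in visits.items() if len(v) < 3)
    if too_few:
        raise ValueError(
            f"subjects with fewer than 3 distinct clinical evaluations are ineligible: {too_few}"
        )
    rng = np.random.default_rng(seed)
    assignments = [
        {s: pd.Timestamp(rng.choice(v)) for s, v in visits.items()} for _ in range(K)
    ]
    return CVPlan(K=K, seed=seed, assignments=assignments)


# ---------------------------------------------------------------------------
# CV run


@dataclass
class CVResult:
    """Tidy per-iteration metrics, optional risk scores, and recorded failures."""

    metrics: pd.DataFrame  # iteration, model, target, feature_set, r2, rmse
    risk: pd.DataFrame | None
    errors: list[dict]


def _fold_masks(dataset: ModelDataset, held: dict[str, pd.Timestamp]) -> tuple[np.ndarray, np.ndarray]:
    frame = dataset.frame
    test = np.zeros(len(frame), dtype=bool)
    for sid, visit in held.items():
        test |= (frame["subject_id"] == sid).to_numpy() & (
            frame["rating_date"] == visit
        ).to_numpy()
    return ~test, test


def run_cv(
    model_names,
    dataset: ModelDataset,
    plan: CVPlan,
    priors: hier.PriorSpec | None = None,
    sampler: hier.SamplerSpec | None = None,
    baseline_params: dict | None = None,
    collect_risk: bool = False,
    threshold: float = 13.0,
) -> CVResult:
    """Fit every model on each training fold and score the held-out rows.

    Metrics are pooled across subjects within an iteration.  With
    ``collect_risk`` the per-row relapse-risk scores (exceedance
    probabilities for Bayesian models, thresholded point predictions for
    the rest) and binary labels y >= threshold are also accumulated.
    A model failure in one iteration is recorded and the run continues.
    """
    unknown = sorted(set(model_names) - set(ALL_MODELS))
    if unknown:
        raise ValueError(f"unknown models {unknown}; expected among {ALL_MODELS}")
    priors = priors or hier.PriorSpec()
    sampler = sampler or hier.SamplerSpec()
    baseline_params = baseline_params or {}

    records: list[dict] = []
    risk_records: list[dict] = []
    errors: list[dict] = []

    for i, held in enumerate(plan.assignments):
        train_mask, test_mask = _fold_masks(dataset, held)
        fold = refit_sleep_features(dataset, train_mask)
        train_frame = fold.frame.loc[train_mask]
        test_frame = fold.frame.loc[test_mask]
        train_ds = ModelDataset(
            frame=train_frame.reset_index(drop=True),
            feature_names=fold.feature_names,
            target_name=fold.target_name,
            feature_set=fold.feature_set,
            sleep_means=fold.sleep_means,
            population_sleep_mean=fold.population_sleep_mean,
            eligibility=fold.eligibility,
        )
        X_test = test_frame[fold.feature_names].to_numpy(dtype=float)
        y_test = test_frame["y"].to_numpy(dtype=float)
        test_subjects = test_frame["subject_id"].tolist()
        fold_seed = (plan.seed * 100_003 + 7919 * i) % (2**31 - 1)

        for name in model_names:
            try:
                if name in BAYESIAN_MODELS:
                    spec = hier.SamplerSpec(
                        chains=sampler.chains,
                        warmup=sampler.warmup,
                        draws=sampler.draws,
                        seed=fold_seed,
                        target_accept=sampler.target_accept,
                    )
                    fit_fn = (
                        hier.fit_hierarchical if name == "hierarchical" else hier.fit_pooled_bayesian
                    )
                    post = fit_fn(train_ds, priors, spec, diagnostics=False)
                    y_hat = hier.point_predict(post, X_test, test_subjects)
                    score = None
                    if collect_risk:
                        draws = hier.posterior_predict(post, X_test, test_subjects, seed=fold_seed)
                        score = np.mean(draws >= threshold, axis=0)
                else:
                    model = bl.BaselineModel(kind=name, seed=fold_seed, **baseline_params)
                    fitted = bl.fit(model, train_ds)
                    y_hat = bl.predict(fitted, X_test, test_subjects)
                    score = (y_hat >= threshold).astype(float) if collect_risk else None
            except Exception as exc:  # noqa: BLE001 - recorded, run continues
                logger.warning("model %s failed in iteration %d: %s", name, i, exc)
                errors.append({"iteration": i, "model": name, "error": str(exc)})
                continue

            records.append(
                {
                    "iteration": i,
                    "model": name,
                    "target": dataset.target_name,
                    "feature_set": dataset.feature_set,
                    "r2": predicted_r2(y_test, y_hat),
                    "rmse": rmse(y_test, y_hat),
                }
            )
            if collect_risk:
                for sid, date, s, y in zip(
                    test_subjects, test_frame["date"], score, y_test
                ):
                    risk_records.append(
                        {
                            "iteration": i,
                            "model": name,
                            "subject_id": sid,
                            "date": date,
                            "target": dataset.target_name,
                            "threshold": threshold,
                            "score": float(s),
                            "label": int(y >= threshold),
                        }
                    )

    metrics = pd.DataFrame(
        records, columns=["iteration", "model", "target", "feature_set", "r2", "rmse"]
    )
    risk = pd.DataFrame(risk_records) if collect_risk else None
    return CVResult(metrics=metrics, risk=risk, errors=errors)


def compare_models(
    cv: CVResult, model_a: str, model_b: str, metric: str = "r2"
) -> tuple[float, float]:
    """Welch two-sample t-test on per-iteration metric values of two models."""
    m = cv.metrics
    a = m.loc[m["model"] == model_a, metric].to_numpy(dtype=float)
    b = m.loc[m["model"] == model_b, metric].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two iterations per model for a t-test")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):  # identical constant score vectors
        return 0.0, 1.0
    return float(t), float(p)


# ---------------------------------------------------------------------------
# importance and descriptive associations


def variable_importance(post: hier.PosteriorSamples) -> pd.DataFrame:
    """Population-weight summary sorted by |t| = |posterior mean| / SD.

    Mirrors the convention that a large mean with a small posterior SD
    marks an important predictor; includes the 95% credible interval.
    """
    draws = post.stacked("mu")  # (S, d)
    names = ["intercept", *post.feature_names]
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    table = pd.DataFrame(
        {
            "predictor": names,
            "mean": mean,
            "sd": sd,
            "ci_low": lo,
            "ci_high": hi,
            "abs_t": np.abs(mean) / sd,
        }
    )
    return table.sort_values("abs_t", ascending=False).reset_index(drop=True)


def descriptive_association(day_table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between self-reported mood and the two ratings.

    ``day_table`` is a day-level join with columns ``mood``, ``hdrs_total``
    and ``ymrs_total``.  Constant columns yield a missing correlation.
    """
    pairs = [("mood", "hdrs_total"), ("mood", "ymrs_total"), ("hdrs_total", "ymrs_total")]
    rows = []
    for a, b in pairs:
        sub = day_table[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"need at least 3 complete pairs for ({a}, {b}); got {len(sub)}")
        x = sub[a].to_numpy(dtype=float)
        y = sub[b].to_numpy(dtype=float)
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            r, p = float("nan"), float("nan")
        else:
            r, p = stats.pearsonr(x, y)
        rows.append({"x": a, "y": b, "n": len(sub), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
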