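"""Feature engineering and alignment of self-assessments with clinical ratings.

The raw daily self-assessment items are turned into the 13 engineered
predictors of the canonical registry (:mod:`moodscale.features`):

* mood is split into a non-positive and a non-negative component, so
  depressed and elevated mood can carry different weights;
* sleep duration is centred on the subject's mean (computed on training
  rows only, to avoid leakage into held-out visits) and split the same way;
* medicine adherence is dummy coded with "taken as prescribed" as the
  reference level;
* everything is scaled onto [-1, 1] by its allowed extreme value.

Each clinical rating is considered valid on the visit day and the three
preceding days, so one rating is expanded into up to four day-level target
rows ("back-filling").  Rows with any missing included item are dropped
(complete case); no imputation is performed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    FEATURE_SETS,
    MEDICINE_CATEGORIES,
    MOOD_GRID,
    NORM_DIVISORS,
    REQUIRED_RAW_ITEMS,
    TARGETS,
)

logger = logging.getLogger(__name__)

BACKFILL_WINDOW = 3  # days before the visit a rating remains valid for


# ---------------------------------------------------------------------------
# elementary transforms


def split_mood(mood: float) -> tuple[float, float]:
    """Split a raw mood score into (mood_negative, mood_positive).

    Exactly one component is nonzero (both zero at neutral mood), which
    lets depressed and elevated mood enter the regression with independent
    weights.
    """
    if not any(math.isclose(mood, g) for g in MOOD_GRID):
        raise ValueError(f"mood value {mood!r} is not on the allowed grid {MOOD_GRID}")
    return (min(mood, 0.0), max(mood, 0.0))


def center_split_sleep(sleep_hours: float, subject_train_mean: float) -> tuple[float, float]:
    """Centre sleep on the subject's (training) mean and split by sign."""
    d = sleep_hours - subject_train_mean
    return (min(d, 0.0), max(d, 0.0))


def encode_medicine(category: str) -> tuple[int, int]:
    """Dummy code adherence as (medicine_omitted, medicine_changed).

    The reference level "taken" maps to (0, 0); it gets no column of its
    own to avoid the dummy-variable trap.
    """
    if category not in MEDICINE_CATEGORIES:
        raise ValueError(
            f"unknown medicine category {category!r}; expected one of {MEDICINE_CATEGORIES}"
        )
    return {"taken": (0, 0), "omitted": (1, 0), "changed": (0, 1)}[category]


def normalize(raw: dict[str, float] | pd.Series) -> dict[str, float]:
    """Scale engineered components onto [-1, 1] by their allowed extremes.

    Sleep deviations have no hard bound; they are divided by 12 h and
    clipped to [-1, 1].
    """
    out: dict[str, float] = {}
    for name, value in dict(raw).items():
        if name not in NORM_DIVISORS:
            raise ValueError(f"unknown feature component {name!r}")
        x = value / NORM_DIVISORS[name]
        if name.startswith("sleep_"):
            x = float(np.clip(x, -1.0, 1.0))
        out[name] = x
    return out


# ---------------------------------------------------------------------------
# rating back-fill


def backfill_ratings(ratings: pd.DataFrame, window: int = BACKFILL_WINDOW) -> pd.DataFrame:
    """Expand each rating to the visit day plus the ``window`` previous days.

    Returns a day-level target table with columns ``subject_id``, ``date``,
    ``rating_date`` and the four target scores.  When windows of two visits
    overlap, a day is assigned to the nearest visit (ties broken toward the
    later visit).
    """
    cols = ["subject_id", "date", "rating_date", *TARGETS]
    if len(ratings) == 0:
        return pd.DataFrame(columns=cols)
    frames = []
    for lag in range(window + 1):
        f = ratings.copy()
        f["rating_date"] = f["date"]
        f["date"] = f["date"] - pd.to_timedelta(lag, unit="D")
        f["_gap"] = lag
        frames.append(f)
    expanded = pd.concat(frames, ignore_index=True)
    expanded = expanded.sort_values(
        ["subject_id", "date", "_gap", "rating_date"],
        ascending=[True, True, True, False],
    )
    expanded = expanded.drop_duplicates(["subject_id", "date"], keep="first")
    return (
        expanded[cols]
        .sort_values(["subject_id", "date"])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass(frozen=True)
class Eligibility:
    """Subject inclusion rule: minimum joined rows or minimum distinct visits."""

    kind: str  # "min_rows" | "min_visits"
    k: int

    def __post_init__(self) -> None:
        if self.kind not in ("min_rows", "min_visits"):
            raise ValueError(f"unknown eligibility kind {self.kind!r}")
        if self.k < 1:
            raise ValueError("eligibility threshold must be >= 1")

    @classmethod
    def parse(cls, spec: "str | Eligibility") -> "Eligibility":
        if isinstance(spec, Eligibility):
            return spec
        s = spec.replace("(", ":").rstrip(")")
        kind, _, k = s.partition(":")
        return cls(kind.strip(), int(k))

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.kind}({self.k})"


@dataclass
class ModelDataset:
    """Aligned design matrix, targets and bookkeeping for one model fit.

    ``frame`` holds one row per (subject, day) with the raw ``sleep_hours``
    (kept so sleep features can be re-centred per CV fold), the normalized
    engineered features in canonical order, the target ``y`` and the
    ``rating_date`` the target was back-filled from.
    """

    frame: pd.DataFrame
    feature_names: list[str]
    target_name: str
    feature_set: str
    sleep_means: dict[str, float]
    population_sleep_mean: float
    eligibility: Eligibility

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.frame["subject_id"].unique())

    @property
    def subject_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.subjects)}

    def design(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, y, subject index per row) with X in canonical feature order."""
        X = self.frame[self.feature_names].to_numpy(dtype=float)
        y = self.frame["y"].to_numpy(dtype=float)
        idx = self.frame["subject_id"].map(self.subject_index).to_numpy(dtype=int)
        return X, y, idx

    # -- persistence --------------------------------------------------------

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(path, index=False)
        sidecar = {
            "feature_names": self.feature_names,
            "target_name": self.target_name,
            "feature_set": self.feature_set,
            "sleep_means": self.sleep_means,
            "population_sleep_mean": self.population_sleep_mean,
            "eligibility": str(self.eligibility),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "ModelDataset":
        path = Path(path)
        frame = pd.read_csv(path, parse_dates=["date", "rating_date"])
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            frame=frame,
            feature_names=meta["feature_names"],
            target_name=meta["target_name"],
            feature_set=meta["feature_set"],
            sleep_means={k: float(v) for k, v in meta["sleep_means"].items()},
            population_sleep_mean=float(meta["population_sleep_mean"]),
            eligibility=Eligibility.parse(meta["eligibility"]),
        )


def compute_sleep_means(assessments: pd.DataFrame) -> tuple[dict[str, float], float]:
    """Per-subject mean sleep duration plus the population fallback mean."""
    valid = assessments.dropna(subset=["sleep_hours"])
    by_subject = valid.groupby("subject_id")["sleep_hours"].mean().to_dict()
    population = float(valid["sleep_hours"].mean()) if len(valid) else 7.0
    return ({k: float(v) for k, v in by_subject.items()}, population)


def engineer_features(
    rows: pd.DataFrame,
    sleep_means: dict[str, float],
    population_sleep_mean: float,
) -> pd.DataFrame:
    """Map raw item columns to the 13 normalized engineered predictors.

    Subjects without a training sleep mean fall back to the population
    training mean (cold start), which is logged.
    """
    out = pd.DataFrame(index=rows.index)
    moods = rows["mood"].to_numpy(dtype=float)
    out["mood_negative"] = np.minimum(moods, 0.0) / NORM_DIVISORS["mood_negative"]
    out["mood_positive"] = np.maximum(moods, 0.0) / NORM_DIVISORS["mood_positive"]

    missing_mean = sorted(set(rows["subject_id"]) - set(sleep_means))
    if missing_mean:
        logger.info(
            "no training sleep mean for subjects %s; using population mean %.2f",
            missing_mean,
            population_sleep_mean,
        )
    means = rows["subject_id"].map(sleep_means).fillna(population_sleep_mean)
    d = rows["sleep_hours"].to_numpy(dtype=float) - means.to_numpy(dtype=float)
    out["sleep_negative"] = np.clip(np.minimum(d, 0.0) / NORM_DIVISORS["sleep_negative"], -1.0, 0.0)
    out["sleep_positive"] = np.clip(np.maximum(d, 0.0) / NORM_DIVISORS["sleep_positive"], 0.0, 1.0)

    med = rows["medicine"].astype("string")
    bad = sorted(set(med.dropna()) - set(MEDICINE_CATEGORIES))
    if bad:
        raise ValueError(f"unknown medicine categories {bad}")
    out["medicine_omitted"] = (med == "omitted").astype(float)
    out["medicine_changed"] = (med == "changed").astype(float)

    for item in ("activity", "alcohol", "anxiety", "irritability", "cognitive", "stress", "mixed_mood"):
        out[item] = rows[item].to_numpy(dtype=float) / NORM_DIVISORS[item]
    return out


def assemble_dataset(
    assessments: pd.DataFrame,
    ratings: pd.DataFrame,
    target_name: str,
    feature_set: str = "all",
    eligibility: str | Eligibility = "min_rows:2",
    sleep_means: tuple[dict[str, float], float] | None = None,
    window: int = BACKFILL_WINDOW,
) -> ModelDataset:
    """Join back-filled ratings with complete self-assessments.

    ``sleep_means`` may be supplied (training-fold means) to generate
    features for held-out rows without leakage; by default means are
    computed from the rows that survive the join and completeness filter.
    """
    if target_name not in TARGETS:
        raise ValueError(f"unknown target {target_name!r}; expected one of {sorted(TARGETS)}")
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature_set {feature_set!r}; expected one of {sorted(FEATURE_SETS)}")
    eligibility = Eligibility.parse(eligibility)

    # duplicate same-day entries: keep the last-entered record
    assessments = assessments.drop_duplicates(["subject_id", "date"], keep="last")

    targets = backfill_ratings(ratings, window=window)
    joined = targets.merge(assessments, on=["subject_id", "date"], how="inner")
    if len(joined) == 0:
        raise ValueError("empty dataset: no self-assessment days fall inside any rating validity window")

    required = list(REQUIRED_RAW_ITEMS[feature_set])
    complete = joined.dropna(subset=required)
    if len(complete) == 0:
        raise ValueError(
            f"empty dataset: complete-case filter removed every row (required items: {required})"
        )

    if eligibility.kind == "min_rows":
        sizes = complete.groupby("subject_id")["date"].transform("size")
        kept = complete[sizes >= eligibility.k]
    else:
        visits = complete.groupby("subject_id")["rating_date"].transform("nunique")
        kept = complete[visits >= eligibility.k]
    if len(kept) == 0:
        raise ValueError(f"empty dataset: eligibility filter {eligibility} excluded every subject")

    if sleep_means is None:
        subj_means, pop_mean = compute_sleep_means(kept)
    else:
        subj_means, pop_mean = sleep_means

    features = engineer_features(kept, subj_means, pop_mean)
    feature_names = list(FEATURE_SETS[feature_set])
    frame = kept[["subject_id", "date", "rating_date", "sleep_hours"]].copy()
    frame["y"] = kept[target_name].astype(float)
    for name in feature_names:
        frame[name] = features[name]
    frame = frame.reset_index(drop=True)

    return ModelDataset(
        frame=frame,
        feature_names=feature_names,
        target_name=target_name,
        feature_set=feature_set,
        sleep_means=subj_means,
        population_sleep_mean=pop_mean,
        eligibility=eligibility,
    )


def refit_sleep_features(dataset: ModelDataset, train_mask: np.ndarray) -> ModelDataset:
    """Re-centre the sleep features using training rows only.

    Used by cross-validation: the per-subject sleep means are recomputed on
    the training rows of a fold and applied to both training and held-out
    rows, so held-out data never influences a training feature.
    """
    frame = dataset.frame.copy()
    train = frame.loc[np.asarray(train_mask, dtype=bool)]
    subj_means, pop_mean = compute_sleep_means(train)
    if {"sleep_negative", "sleep_positive"} & set(dataset.feature_names):
        means = frame["subject_id"].map(subj_means).fillna(pop_mean)
        d = frame["sleep_hours"].to_numpy(dtype=float) - means.to_numpy(dtype=float)
        frame["sleep_negative"] = np.clip(np.minimum(d, 0.0) / 12.0, -1.0, 0.0)
        frame["sleep_positive"] = np.clip(np.maximum(d, 0.0) / 12.0, 0.0, 1.0)
    return ModelDataset(
        frame=frame,
        feature_names=dataset.feature_names,
        target_name=dataset.target_name,
        feature_set=dataset.feature_set,
        sleep_means=subj_means,
        population_sleep_mean=pop_mean,
        eligibility=dataset.eligibility,
    )
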