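"""Synthetic longitudinal cohort generator.

Emulates the structure of a smartphone-monitoring study in bipolar
disorder: ~84 subjects followed for nine months, daily self-assessments
(with missing days), and up to five clinician visits per subject producing
HDRS/YMRS ratings.  Ratings are generated from a known hierarchical linear
model on the engineered features, so every downstream stage (preprocessing,
hierarchical fit, cross-validation, risk scoring) can be tested against the
ground truth without access to real patient data.

Generative sketch, per subject j:

* a latent affective valence z_t follows a slowly mixing AR(1) process
  (negative = depressive drift, positive = manic drift);
* daily items are noisy monotone maps of z_t within their declared ranges;
* subject coefficients (alpha_j, beta_j) ~ Normal(mu_true, tau_true);
* on visit days the engineered feature vector x of that day (the same
  transforms the preprocessing module applies, with sleep centred on the
  subject's true mean) yields the depression total
  y = alpha_j + beta_j' x + Normal(0, sigma_true), rounded and clipped to
  scale bounds; the mania total uses a deterministic mirror of the same
  weights (mood/sleep split pairs negated and swapped) so elevated mood
  raises the mania score;
* item-1 scores are derived from the totals; whole-day records are then
  dropped at ``missing_rate`` and optional items at ``optional_missing_rate``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess
from .features import FEATURES, MOOD_GRID, TARGETS, n_weights, weight_names
from .reference import published_weight_table

_AR_PHI = 0.99  # day-to-day persistence of the latent valence (episodes last months)
_NOISE_PHI = 0.9  # persistence of day-level reporting noise

#: Protocol-like visit placement as fractions of the study length
#: (baseline, ~4 weeks, ~3/6/9 months).
_VISIT_FRACTIONS_5 = (0.02, 0.11, 0.33, 0.66, 0.98)


def _default_mu_true() -> np.ndarray:
    table = published_weight_table("hdrs_total").set_index("predictor")
    return np.array([table.loc[name, "mu_mean"] for name in weight_names()], dtype=float)


def _default_tau_true() -> np.ndarray:
    table = published_weight_table("hdrs_total").set_index("predictor")
    return np.array([table.loc[name, "tau_mean"] for name in weight_names()], dtype=float)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the real study's shape: 84 subjects, 270 days of
    follow-up, 5 visits, ~30% of daily entries missing (≈190 completed
    entries per subject), ground-truth weights anchored to the published
    population estimates and residual SD equal to the published in-sample
    RMSE.
    """

    n_subjects: int = 84
    n_days: int = 270
    n_visits: int = 5
    missing_rate: float = 0.3
    optional_missing_rate: float = 0.03
    item_noise: float = 0.5
    mu_true: np.ndarray = field(default_factory=_default_mu_true)
    tau_true: np.ndarray = field(default_factory=_default_tau_true)
    sigma_true: float = 2.41
    seed: int = 0
    clip_ratings: bool = True  # disable for parameter-recovery diagnostics

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu_true", np.asarray(self.mu_true, dtype=float))
        object.__setattr__(self, "tau_true", np.asarray(self.tau_true, dtype=float))
        if min(self.n_subjects, self.n_days, self.n_visits) < 1:
            raise ValueError("n_subjects, n_days and n_visits must be positive")
        if not (0.0 <= self.missing_rate <= 1.0 and 0.0 <= self.optional_missing_rate <= 1.0):
            raise ValueError("missing rates must lie in [0, 1]")
        if self.item_noise < 0 or self.sigma_true < 0:
            raise ValueError("item_noise and sigma_true must be nonnegative")
        d = n_weights()
        if self.mu_true.shape != (d,) or self.tau_true.shape != (d,):
            raise ValueError(f"mu_true and tau_true must have length {d} (intercept + features)")
        if np.any(self.tau_true < 0):
            raise ValueError("tau_true must be nonnegative")
        if self.n_visits * 4 > self.n_days:
            raise ValueError(
                f"infeasible config: {self.n_visits} visits need more than {self.n_days} days"
            )


@dataclass
class GroundTruth:
    """True parameters behind a generated cohort (primary target: hdrs_total)."""

    mu_true: np.ndarray
    tau_true: np.ndarray
    sigma_true: float
    alpha_true: np.ndarray  # (n_subjects,)
    beta_true: np.ndarray  # (n_subjects, n_features)
    subject_ids: list[str]
    sleep_mean_true: np.ndarray | None = None  # per-subject true sleep mean (h)
    feature_names: list[str] = field(default_factory=lambda: list(FEATURES))

    def write(self, path: str | Path) -> None:
        payload = {
            "weight_order": weight_names(),
            "feature_names": self.feature_names,
            "subject_ids": self.subject_ids,
            "mu_true": self.mu_true.tolist(),
            "tau_true": self.tau_true.tolist(),
            "sigma_true": self.sigma_true,
            "alpha_true": self.alpha_true.tolist(),
            "beta_true": self.beta_true.tolist(),
            "sleep_mean_true": None
            if self.sleep_mean_true is None
            else self.sleep_mean_true.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        p = json.loads(Path(path).read_text())
        sleep = p.get("sleep_mean_true")
        return cls(
            mu_true=np.array(p["mu_true"]),
            tau_true=np.array(p["tau_true"]),
            sigma_true=float(p["sigma_true"]),
            alpha_true=np.array(p["alpha_true"]),
            beta_true=np.array(p["beta_true"]),
            subject_ids=list(p["subject_ids"]),
            sleep_mean_true=None if sleep is None else np.array(sleep),
            feature_names=list(p["feature_names"]),
        )


def mirror_weights(theta: np.ndarray) -> np.ndarray:
    """Mania-scale weights as a negate-and-swap mirror of depression weights.

    The weight on the negative mood component becomes (minus) the weight on
    the positive component and vice versa (same for the sleep split), so a
    cohort whose depression score rises with depressed mood has a mania
    score that rises with elevated mood.  All other weights, including the
    intercept, carry over unchanged.
    """
    theta = np.asarray(theta, dtype=float)
    names = weight_names() if theta.shape[-1] == n_weights() else list(FEATURES)
    idx = {n: i for i, n in enumerate(names)}
    out = theta.copy()
    for neg, pos in (("mood_negative", "mood_positive"), ("sleep_negative", "sleep_positive")):
        out[..., idx[neg]] = -theta[..., idx[pos]]
        out[..., idx[pos]] = -theta[..., idx[neg]]
    return out


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float = 1.0) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sd``."""
    z = np.empty(n)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1.0 - phi**2) if n > 1 else []
    for t in range(1, n):
        z[t] = phi * z[t - 1] + innov[t - 1]
    return sd * z


def _visit_days(n_days: int, n_visits: int, rng: np.random.Generator) -> np.ndarray:
    if n_visits == 5:
        fracs = np.array(_VISIT_FRACTIONS_5)
    else:
        fracs = np.linspace(0.02, 0.98, n_visits)
    base = np.round(fracs * (n_days - 1)).astype(int)
    days = []
    prev = -1
    for b in base:
        lo = max(prev + 1, b - 2)
        hi = min(n_days - 1, b + 2)
        if lo > hi:
            lo = hi = min(n_days - 1, prev + 1)
        day = int(rng.integers(lo, hi + 1))
        day = max(day, prev + 1)
        days.append(min(day, n_days - 1))
        prev = days[-1]
    return np.unique(days)


def _snap_to_grid(values: np.ndarray) -> np.ndarray:
    grid = np.asarray(MOOD_GRID)
    return grid[np.argmin(np.abs(values[:, None] - grid[None, :]), axis=1)]


def _ordinal(raw: np.ndarray, high: int) -> np.ndarray:
    return np.clip(np.round(raw), 0, high).astype(int)


def _derive_item1(total: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    noisy = frac * np.maximum(total, 0.0) + rng.normal(0.0, 0.15, size=total.shape)
    item1 = np.clip(np.round(noisy), 0, 4)
    return np.minimum(item1, np.floor(np.maximum(total, 0.0))).astype(int)


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (self-assessments, clinical ratings, ground truth).

    Deterministic given ``config.seed``.  The assessments table has one row
    per subject-day that survived the missingness process; the ratings
    table has one row per visit with strictly increasing dates within each
    subject.
    """
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp("2015-01-01")
    subject_ids = [f"S{j:03d}" for j in range(1, config.n_subjects + 1)]

    theta = config.mu_true + config.tau_true * rng.standard_normal(
        (config.n_subjects, n_weights())
    )
    truth = GroundTruth(
        mu_true=config.mu_true.copy(),
        tau_true=config.tau_true.copy(),
        sigma_true=config.sigma_true,
        alpha_true=theta[:, 0].copy(),
        beta_true=theta[:, 1:].copy(),
        subject_ids=subject_ids,
    )

    assessment_rows: list[pd.DataFrame] = []
    rating_rows: list[pd.DataFrame] = []
    sleep_means: list[float] = []

    for j, sid in enumerate(subject_ids):
        # latent affective valence, slowly mixing around 0
        z = _ar1(rng, config.n_days, _AR_PHI)
        burden = np.abs(z)

        sleep_mean = 7.0 + rng.normal(0.0, 0.7)
        sleep_means.append(sleep_mean)
        # iid day-level reporting noise on top of the persistent latent state
        noise = lambda: rng.normal(0.0, config.item_noise, size=config.n_days)

        mood = _snap_to_grid(1.3 * z + noise())
        activity = np.clip(np.round(0.8 * z + noise()), -3, 3).astype(int)
        sleep = np.clip(np.round((sleep_mean - 1.2 * z + noise()) * 2) / 2, 0.0, 24.0)
        anxiety = _ordinal(0.6 * np.maximum(-z, 0) + 0.2 * burden + noise(), 2)
        irritability = _ordinal(0.5 * np.maximum(z, 0) + 0.2 * burden + noise(), 2)
        cognitive = _ordinal(0.5 * np.maximum(-z, 0) + 0.2 * burden + noise(), 2)
        stress = _ordinal(0.6 * burden + noise(), 2)
        alcohol = np.minimum(rng.poisson(0.8, size=config.n_days), 10).astype(int)
        # adherence comes in persistent phases rather than daily coin flips
        adh = _ar1(rng, config.n_days, _NOISE_PHI)
        medicine = np.where(
            adh > 1.65, "omitted", np.where(adh + 0.6 * burden > 1.8, "changed", "taken")
        )
        mixed = (_ar1(rng, config.n_days, _NOISE_PHI) + 0.5 * burden > 2.0).astype(int)

        day_frame = pd.DataFrame(
            {
                "subject_id": sid,
                "date": start + pd.to_timedelta(np.arange(config.n_days), unit="D"),
                "activity": activity,
                "alcohol": alcohol,
                "anxiety": anxiety,
                "irritability": irritability,
                "cognitive": cognitive,
                "medicine": medicine,
                "mixed_mood": mixed,
                "mood": mood,
                "sleep_hours": sleep,
                "stress": stress,
            }
        )

        # ratings on visit days, from that day's engineered features
        visits = _visit_days(config.n_days, config.n_visits, rng)
        x = np.empty((len(visits), len(FEATURES)))
        for i, day in enumerate(visits):
            raw: dict[str, float] = {}
            raw["mood_negative"], raw["mood_positive"] = preprocess.split_mood(float(mood[day]))
            raw["sleep_negative"], raw["sleep_positive"] = preprocess.center_split_sleep(
                float(sleep[day]), sleep_mean
            )
            om, ch = preprocess.encode_medicine(str(medicine[day]))
            raw["medicine_omitted"], raw["medicine_changed"] = om, ch
            for item in ("activity", "alcohol", "anxiety", "irritability", "cognitive", "stress"):
                raw[item] = float(day_frame[item].iloc[day])
            raw["mixed_mood"] = float(mixed[day])
            normed = preprocess.normalize(raw)
            x[i] = [normed[name] for name in FEATURES]

        lin_h = theta[j, 0] + x @ theta[j, 1:]
        theta_y = mirror_weights(theta[j])
        lin_y = theta_y[0] + x @ theta_y[1:]
        hdrs = lin_h + rng.normal(0.0, config.sigma_true, size=len(visits))
        ymrs = lin_y + rng.normal(0.0, config.sigma_true, size=len(visits))
        if config.clip_ratings:
            hdrs = np.clip(np.round(hdrs), *TARGETS["hdrs_total"]).astype(int)
            ymrs = np.clip(np.round(ymrs), *TARGETS["ymrs_total"]).astype(int)

        rating_rows.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "date": start + pd.to_timedelta(visits, unit="D"),
                    "hdrs_total": hdrs,
                    "ymrs_total": ymrs,
                    "hdrs_item1": _derive_item1(np.asarray(hdrs, dtype=float), 0.09, rng),
                    "ymrs_item1": _derive_item1(np.asarray(ymrs, dtype=float), 0.085, rng),
                }
            )
        )

        # missingness: whole days first, then optional items
        keep = rng.random(config.n_days) >= config.missing_rate
        day_frame = day_frame.loc[keep].reset_index(drop=True)
        for item in ("alcohol", "anxiety", "irritability", "cognitive", "mixed_mood", "stress"):
            drop = rng.random(config.n_days)[keep] < config.optional_missing_rate
            day_frame[item] = day_frame[item].astype("Int64").mask(drop)
        assessment_rows.append(day_frame)

    truth.sleep_mean_true = np.array(sleep_means)
    assessments = pd.concat(assessment_rows, ignore_index=True)
    ratings = pd.concat(rating_rows, ignore_index=True)
    return assessments, ratings, truth


# ---------------------------------------------------------------------------
# persistence

_ASSESSMENT_COLS = [
    "subject_id", "date", "activity", "alcohol", "anxiety", "irritability",
    "cognitive", "medicine", "mixed_mood", "mood", "sleep_hours", "stress",
]
_RATING_COLS = ["subject_id", "date", "hdrs_total", "ymrs_total", "hdrs_item1", "ymrs_item1"]
_OPTIONAL_INT_ITEMS = ("alcohol", "anxiety", "irritability", "cognitive", "mixed_mood", "stress")
_ITEM_RANGES = {
    "activity": (-3, 3),
    "alcohol": (0, 10),
    "anxiety": (0, 2),
    "irritability": (0, 2),
    "cognitive": (0, 2),
    "mixed_mood": (0, 1),
    "stress": (0, 2),
    "sleep_hours": (0.0, 24.0),
}


def write_cohort(assessments: pd.DataFrame, ratings: pd.DataFrame, path: str | Path) -> None:
    """Write ``self_assessments.csv`` and ``clinical_ratings.csv`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    a = assessments.copy()
    if len(a):
        a["date"] = pd.to_datetime(a["date"]).dt.strftime("%Y-%m-%d")
    r = ratings.copy()
    if len(r):
        r["date"] = pd.to_datetime(r["date"]).dt.strftime("%Y-%m-%d")
    a.reindex(columns=_ASSESSMENT_COLS).to_csv(path / "self_assessments.csv", index=False)
    r.reindex(columns=_RATING_COLS).to_csv(path / "clinical_ratings.csv", index=False)


def _check(condition: bool, line: int, filename: str, message: str, errors: list[str]) -> None:
    if not condition:
        errors.append(f"{filename}, line {line}: {message}")


def read_cohort(path: str | Path, validate: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`.

    With ``validate=True`` malformed rows are reported with their CSV line
    numbers (header = line 1).
    """
    path = Path(path)
    assessments = pd.read_csv(
        path / "self_assessments.csv",
        parse_dates=["date"],
        dtype={item: "Int64" for item in _OPTIONAL_INT_ITEMS} | {"activity": "Int64"},
    )
    ratings = pd.read_csv(path / "clinical_ratings.csv", parse_dates=["date"])
    if validate:
        errors: list[str] = []
        for i, row in assessments.iterrows():
            line = int(i) + 2
            for item, (lo, hi) in _ITEM_RANGES.items():
                v = row[item]
                if pd.notna(v):
                    _check(lo <= v <= hi, line, "self_assessments.csv",
                           f"{item}={v} outside [{lo}, {hi}]", errors)
            if pd.notna(row["mood"]):
                _check(float(row["mood"]) in MOOD_GRID, line, "self_assessments.csv",
                       f"mood={row['mood']} not on grid", errors)
            if pd.notna(row["medicine"]):
                _check(row["medicine"] in ("taken", "omitted", "changed"), line,
                       "self_assessments.csv", f"medicine={row['medicine']!r} unknown", errors)
        dup = assessments.duplicated(["subject_id", "date"])
        for i in np.flatnonzero(dup.to_numpy()):
            _check(False, int(i) + 2, "self_assessments.csv", "duplicate subject/date", errors)
        for i, row in ratings.iterrows():
            line = int(i) + 2
            for name, (lo, hi) in TARGETS.items():
                _check(lo <= row[name] <= hi, line, "clinical_ratings.csv",
                       f"{name}={row[name]} outside [{lo}, {hi}]", errors)
            _check(row["hdrs_item1"] <= row["hdrs_total"], line, "clinical_ratings.csv",
                   "hdrs_item1 exceeds hdrs_total", errors)
            _check(row["ymrs_item1"] <= row["ymrs_total"], line, "clinical_ratings.csv",
                   "ymrs_item1 exceeds ymrs_total", errors)
        for _, grp in ratings.groupby("subject_id"):
            dates = grp["date"].to_numpy()
            for k in np.flatnonzero(dates[1:] <= dates[:-1]):
                _check(False, int(grp.index[k + 1]) + 2, "clinical_ratings.csv",
                       "visit dates not strictly increasing", errors)
        if errors:
            raise ValueError("malformed cohort files:\n" + "\n".join(errors))
    return assessments, ratings
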