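"""Canonical feature registry for the engineered self-assessment predictors.

Every module that builds, consumes or reports a weight vector uses the
ordering defined here: index 0 of a population weight vector is the
intercept, followed by :data:`FEATURES` in order.
"""

from __future__ import annotations

#: Allowed values of the raw mood item (a bipolar scale with extra half
#: steps near neutral).
MOOD_GRID: tuple[float, ...] = (-3.0, -2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

#: Engineered predictors in canonical order.  The raw mood and (mean-centred)
#: sleep items are each split into a non-positive and a non-negative
#: component; medicine adherence is dummy-coded with "taken as prescribed"
#: as the reference level.
FEATURES: tuple[str, ...] = (
    "activity",
    "alcohol",
    "anxiety",
    "irritability",
    "cognitive",
    "medicine_omitted",
    "medicine_changed",
    "mixed_mood",
    "mood_negative",
    "mood_positive",
    "sleep_negative",
    "sleep_positive",
    "stress",
)

#: Predictor subsets selectable when assembling a model dataset.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "all": FEATURES,
    "mandatory": (
        "activity",
        "medicine_omitted",
        "medicine_changed",
        "mood_negative",
        "mood_positive",
        "sleep_negative",
        "sleep_positive",
    ),
    "mood": ("mood_negative", "mood_positive"),
}

#: Divisor used to map each engineered component onto [-1, 1].  Sleep
#: deviations have no hard bound; they are divided by 12 h and clipped.
NORM_DIVISORS: dict[str, float] = {
    "activity": 3.0,
    "alcohol": 10.0,
    "anxiety": 2.0,
    "irritability": 2.0,
    "cognitive": 2.0,
    "medicine_omitted": 1.0,
    "medicine_changed": 1.0,
    "mixed_mood": 1.0,
    "mood_negative": 3.0,
    "mood_positive": 3.0,
    "sleep_negative": 12.0,
    "sleep_positive": 12.0,
    "stress": 2.0,
}

#: Raw self-assessment columns as stored on disk.
RAW_ITEMS: tuple[str, ...] = (
    "activity",
    "alcohol",
    "anxiety",
    "irritability",
    "cognitive",
    "medicine",
    "mixed_mood",
    "mood",
    "sleep_hours",
    "stress",
)

#: Items the app requires every day; the rest may be left blank.
MANDATORY_ITEMS: tuple[str, ...] = ("activity", "medicine", "mood", "sleep_hours")

MEDICINE_CATEGORIES: tuple[str, ...] = ("taken", "omitted", "changed")

#: Clinical rating targets and their scale bounds.
TARGETS: dict[str, tuple[int, int]] = {
    "hdrs_total": (0, 52),
    "ymrs_total": (0, 60),
    "hdrs_item1": (0, 4),
    "ymrs_item1": (0, 4),
}

#: Raw items that must be observed for a row to enter a given feature set
#: (complete-case analysis: rows with any missing included item are dropped).
REQUIRED_RAW_ITEMS: dict[str, tuple[str, ...]] = {
    "all": RAW_ITEMS,
    "mandatory": MANDATORY_ITEMS,
    "mood": ("mood",),
}


def weight_names() -> list[str]:
    """Names of a full population weight vector: intercept then features."""
    return ["intercept", *FEATURES]


def n_weights() -> int:
    return 1 + len(FEATURES)
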