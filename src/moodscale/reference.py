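"""Published population-weight summaries for the MONARCA II cohort models.

These are the reported posterior summaries (mean, SD, 95% credible interval
and |t| = |mean|/SD variable importance) of the population-level weights mu
and between-subject SDs tau in the hierarchical models of HDRS and YMRS
total scores fitted to the original clinical cohort.  They serve two
purposes here: worked-example checks of the importance arithmetic, and
realistic default ground-truth weights for the synthetic cohort generator.

Columns per row: (predictor, mu_mean, mu_sd, mu_ci_low, mu_ci_high, abs_t,
tau_mean, tau_sd).
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = [
    "predictor",
    "mu_mean",
    "mu_sd",
    "mu_ci_low",
    "mu_ci_high",
    "abs_t",
    "tau_mean",
    "tau_sd",
]

_HDRS_ROWS = [
    ("intercept", 6.43, 0.66, 5.13, 7.73, 9.67, 4.10, 0.50),
    ("mood_negative", -9.11, 1.40, -11.94, -6.43, 6.51, 0.56, 0.40),
    ("sleep_negative", -6.48, 1.66, -9.72, -3.19, 3.89, 0.42, 0.31),
    ("mixed_mood", 2.11, 0.67, 0.79, 3.42, 3.15, 0.44, 0.32),
    ("anxiety", 2.26, 0.86, 0.58, 3.96, 2.63, 0.38, 0.28),
    ("medicine_changed", -1.81, 0.71, -3.19, -0.40, 2.55, 0.35, 0.27),
    ("cognitive", 1.09, 0.73, -0.35, 2.48, 1.50, 0.43, 0.32),
    ("mood_positive", -2.80, 1.94, -6.59, 0.94, 1.44, 0.42, 0.32),
    ("sleep_positive", 2.83, 2.05, -1.09, 6.90, 1.38, 0.41, 0.31),
    ("activity", 0.53, 0.61, -0.66, 1.71, 0.88, 0.50, 0.35),
    ("stress", 0.56, 0.73, -0.86, 1.99, 0.76, 0.50, 0.36),
    ("alcohol", 0.59, 1.01, -1.39, 2.54, 0.59, 0.41, 0.31),
    ("medicine_omitted", 0.52, 0.97, -1.38, 2.42, 0.54, 0.37, 0.28),
    ("irritability", 0.05, 0.74, -1.41, 1.49, 0.06, 0.59, 0.42),
]

_YMRS_ROWS = [
    ("intercept", 3.10, 0.68, 1.79, 4.46, 4.59, 4.35, 0.50),
    ("mood_positive", 12.83, 1.90, 9.09, 16.53, 6.75, 0.57, 0.42),
    ("mood_negative", 3.42, 1.30, 0.87, 5.99, 2.63, 0.66, 0.46),
    ("irritability", 1.31, 0.69, -0.05, 2.68, 1.90, 0.71, 0.47),
    ("mixed_mood", 1.02, 0.62, -0.20, 2.21, 1.65, 0.54, 0.36),
    ("stress", 1.15, 0.70, -0.21, 2.54, 1.65, 1.24, 0.53),
    ("sleep_positive", -2.69, 1.84, -6.30, 0.84, 1.46, 0.40, 0.30),
    ("activity", -0.78, 0.56, -1.88, 0.30, 1.39, 0.63, 0.41),
    ("medicine_changed", 0.46, 0.71, -0.99, 1.81, 0.64, 0.80, 0.48),
    ("cognitive", 0.41, 0.69, -0.92, 1.78, 0.59, 0.94, 0.54),
    ("anxiety", 0.18, 0.80, -1.40, 1.73, 0.23, 0.69, 0.48),
    ("sleep_negative", 0.30, 1.50, -2.63, 3.26, 0.20, 0.43, 0.32),
    ("alcohol", 0.05, 0.93, -1.77, 1.86, 0.06, 0.39, 0.30),
    ("medicine_omitted", -0.02, 0.90, -1.78, 1.75, 0.02, 0.41, 0.31),
]


def published_weight_table(target: str) -> pd.DataFrame:
    """Published weight summary for ``hdrs_total`` or ``ymrs_total``."""
    if target == "hdrs_total":
        rows = _HDRS_ROWS
    elif target == "ymrs_total":
        rows = _YMRS_ROWS
    else:
        raise ValueError(
            f"no published weight table for target {target!r}; "
            "available: hdrs_total, ymrs_total"
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


#: Worked-example rows used to check the |t| = |mean|/SD importance
#: arithmetic against the printed values (rows whose printed mean/SD
#: reproduce the printed |t| to two decimals).
WORKED_T_EXAMPLES: dict[str, tuple[str, str]] = {
    "hdrs_mood_negative": ("hdrs_total", "mood_negative"),
    "hdrs_mixed_mood": ("hdrs_total", "mixed_mood"),
    "ymrs_mood_positive": ("ymrs_total", "mood_positive"),
    "ymrs_mood_negative": ("ymrs_total", "mood_negative"),
}
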