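"""Feature engineering, back-fill and dataset assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import moodscale as ms
from moodscale.features import FEATURE_SETS, MOOD_GRID
from moodscale.preprocess import backfill_ratings, engineer_features


@pytest.mark.parametrize(
    "mood, expected",
    [(0.0, (0.0, 0.0)), (-2.0, (-2.0, 0.0)), (0.5, (0.0, 0.5)), (3.0, (0.0, 3.0))],
)
def test_split_mood(mood, expected):
    assert ms.split_mood(mood) == expected


def test_split_mood_rejects_off_grid_value():
    with pytest.raises(ValueError, match="grid"):
        ms.split_mood(1.5)


@pytest.mark.parametrize(
    "sleep, mean, expected",
    [(7.0, 7.0, (0.0, 0.0)), (5.0, 8.0, (-3.0, 0.0)), (10.0, 8.0, (0.0, 2.0))],
)
def test_center_split_sleep(sleep, mean, expected):
    assert ms.center_split_sleep(sleep, mean) == expected


@pytest.mark.parametrize(
    "category, expected",
    [("taken", (0, 0)), ("omitted", (1, 0)), ("changed", (0, 1))],
)
def test_encode_medicine(category, expected):
    # "taken as prescribed" is the reference level and gets no column
    assert ms.encode_medicine(category) == expected


def test_encode_medicine_rejects_unknown_category():
    with pytest.raises(ValueError, match="unknown medicine"):
        ms.encode_medicine("skipped")


def test_normalize_scale_endpoints_and_zero_fixed_point():
    assert ms.normalize({"mood_negative": -3.0})["mood_negative"] == -1.0
    assert ms.normalize({"anxiety": 1.0})["anxiety"] == 0.5
    zeros = {name: 0.0 for name in FEATURE_SETS["all"]}
    assert all(v == 0.0 for v in ms.normalize(zeros).values())
    # sleep deviations beyond 12 h clip to the unit interval
    assert ms.normalize({"sleep_positive": 15.0})["sleep_positive"] == 1.0


@given(st.sampled_from(MOOD_GRID))
def test_mood_split_components_are_exclusive_and_reassemble(mood):
    neg, pos = ms.split_mood(mood)
    assert neg * pos == 0.0
    assert neg + pos == mood
    assert neg <= 0.0 <= pos


def _ratings(rows):
    return pd.DataFrame(
        [
            {
                "subject_id": s,
                "date": pd.Timestamp("2015-01-01") + pd.Timedelta(days=d),
                "hdrs_total": h,
                "ymrs_total": 0,
                "hdrs_item1": 0,
                "ymrs_item1": 0,
            }
            for s, d, h in rows
        ]
    )


class TestBackfill:
    def test_single_rating_expands_to_four_days(self):
        out = backfill_ratings(_ratings([("A", 10, 15)]))
        assert len(out) == 4
        days = (out["date"] - pd.Timestamp("2015-01-01")).dt.days.tolist()
        assert days == [7, 8, 9, 10]
        assert (out["hdrs_total"] == 15).all()

    def test_overlapping_windows_resolved_to_nearest_visit(self):
        out = backfill_ratings(_ratings([("A", 10, 1), ("A", 12, 2)]))
        day9 = out[(out["date"] - pd.Timestamp("2015-01-01")).dt.days == 9]
        assert day9["hdrs_total"].item() == 1  # day-10 visit is nearer
        assert not out.duplicated(["subject_id", "date"]).any()

    def test_empty_ratings_give_empty_table(self):
        out = backfill_ratings(_ratings([]))
        assert len(out) == 0

    def test_expansion_bounded_by_four_rows_per_rating(self, small_cohort):
        _, _, ratings, _ = small_cohort
        out = backfill_ratings(ratings)
        assert len(out) <= 4 * len(ratings)


def _brute_force_join_count(assessments, ratings, window=3):
    """Oracle: for each rating, count days in its window with an assessment,
    resolving overlaps to the nearest (later on tie) visit."""
    count = 0
    days = {(r.subject_id, r.date) for r in assessments.itertuples()}
    for r in ratings.itertuples():
        same = ratings[ratings["subject_id"] == r.subject_id]
        for lag in range(window + 1):
            day = r.date - pd.Timedelta(days=lag)
            if (r.subject_id, day) not in days:
                continue
            gaps = (same["date"] - day).dt.days
            valid = same[(gaps >= 0) & (gaps <= window)]
            best = valid.loc[
                ((valid["date"] - day).dt.days).sort_values(kind="stable").index
            ]
            winner = best.iloc[0]["date"]
            if winner == r.date:
                count += 1
    return count


class TestAssemble:
    def test_row_count_matches_brute_force_join_oracle(self):
        config = ms.SimConfig(
            n_subjects=3, n_days=60, n_visits=8, missing_rate=0.2,
            optional_missing_rate=0.0, seed=13,
        )
        assessments, ratings, _ = ms.generate_cohort(config)
        dataset = ms.assemble_dataset(assessments, ratings, "hdrs_total", "all", "min_rows:1")
        assert len(dataset) == _brute_force_join_count(assessments, ratings)

    @pytest.mark.parametrize("feature_set, n", [("all", 13), ("mandatory", 7), ("mood", 2)])
    def test_feature_subsets_have_documented_sizes(self, small_cohort, feature_set, n):
        _, assessments, ratings, _ = small_cohort
        ds = ms.assemble_dataset(assessments, ratings, "hdrs_total", feature_set)
        assert len(ds.feature_names) == n

    def test_min_visits_eligibility_excludes_sparse_subjects(self):
        config = ms.SimConfig(n_subjects=4, n_days=40, n_visits=2, seed=3,
                              missing_rate=0.0, optional_missing_rate=0.0)
        assessments, ratings, _ = ms.generate_cohort(config)
        with pytest.raises(ValueError, match="eligibility"):
            ms.assemble_dataset(assessments, ratings, "hdrs_total", "all", "min_visits:3")

    def test_duplicate_same_day_assessment_keeps_last_record(self):
        config = ms.SimConfig(n_subjects=2, n_days=30, n_visits=3, seed=3,
                              missing_rate=0.0, optional_missing_rate=0.0)
        assessments, ratings, _ = ms.generate_cohort(config)
        dup = assessments.iloc[[0]].copy()
        dup["mood"] = 3.0 if assessments.iloc[0]["mood"] != 3.0 else -3.0
        stacked = pd.concat([assessments, dup], ignore_index=True)
        ds = ms.assemble_dataset(stacked, ratings, "hdrs_total", "mood", "min_rows:1")
        row = ds.frame[(ds.frame["subject_id"] == dup.iloc[0]["subject_id"])
                       & (ds.frame["date"] == dup.iloc[0]["date"])]
        if len(row):  # the duplicated day fell inside a rating window
            expected = ms.normalize(dict(zip(("mood_negative", "mood_positive"),
                                             ms.split_mood(dup.iloc[0]["mood"]))))
            assert row["mood_positive"].item() == expected["mood_positive"]

    def test_exclusivity_products_vanish_on_every_row(self, small_dataset):
        f = small_dataset.frame
        assert (f["mood_negative"] * f["mood_positive"] == 0).all()
        assert (f["sleep_negative"] * f["sleep_positive"] == 0).all()
        assert (f["medicine_omitted"] * f["medicine_changed"] == 0).all()
        assert (f["mood_negative"] <= 0).all() and (f["mood_positive"] >= 0).all()
        assert f[small_dataset.feature_names].abs().le(1.0).all().all()

    def test_complete_case_drops_rows_with_missing_optional_items(self):
        config = ms.SimConfig(n_subjects=6, n_days=80, n_visits=5, seed=4,
                              missing_rate=0.0, optional_missing_rate=0.5)
        assessments, ratings, _ = ms.generate_cohort(config)
        ds_all = ms.assemble_dataset(assessments, ratings, "hdrs_total", "all", "min_rows:1")
        ds_mood = ms.assemble_dataset(assessments, ratings, "hdrs_total", "mood", "min_rows:1")
        assert len(ds_all) < len(ds_mood)  # mandatory items are never missing
        assert not ds_all.frame[ds_all.feature_names].isna().any().any()

    def test_cold_start_subject_uses_population_sleep_mean(self, small_cohort):
        _, assessments, ratings, _ = small_cohort
        means = {"S001": 7.5}  # every other subject is cold-started
        rows = assessments.dropna(subset=["sleep_hours"]).head(20)
        feats = engineer_features(rows, means, population_sleep_mean=8.0)
        other = rows["subject_id"] != "S001"
        d = rows.loc[other, "sleep_hours"] - 8.0
        expected = np.clip(np.minimum(d, 0) / 12.0, -1, 0)
        assert np.allclose(feats.loc[other, "sleep_negative"], expected)


def test_sleep_mean_refit_never_uses_held_out_rows(small_dataset):
    """Leakage mutation test: perturbing a held-out row's sleep duration
    must not change any training-row feature."""
    n = len(small_dataset)
    train_mask = np.ones(n, dtype=bool)
    train_mask[n - 5 :] = False

    fold_a = ms.preprocess.refit_sleep_features(small_dataset, train_mask)
    mutated = ms.preprocess.ModelDataset(
        frame=small_dataset.frame.copy(),
        feature_names=small_dataset.feature_names,
        target_name=small_dataset.target_name,
        feature_set=small_dataset.feature_set,
        sleep_means=small_dataset.sleep_means,
        population_sleep_mean=small_dataset.population_sleep_mean,
        eligibility=small_dataset.eligibility,
    )
    mutated.frame.loc[~train_mask, "sleep_hours"] += 5.0
    fold_b = ms.preprocess.refit_sleep_features(mutated, train_mask)
    pd.testing.assert_frame_equal(
        fold_a.frame.loc[train_mask].reset_index(drop=True),
        fold_b.frame.loc[train_mask].reset_index(drop=True),
    )
    assert fold_a.sleep_means == fold_b.sleep_means


def test_dataset_round_trips_through_csv(small_dataset, tmp_path):
    small_dataset.write(tmp_path / "dataset.csv")
    loaded = ms.ModelDataset.read(tmp_path / "dataset.csv")
    pd.testing.assert_frame_equal(small_dataset.frame, loaded.frame, check_dtype=False)
    assert loaded.feature_names == small_dataset.feature_names
    assert loaded.sleep_means == pytest.approx(small_dataset.sleep_means)
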