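"""CV design, metrics, model comparison, importance and correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import moodscale as ms
from moodscale.evaluation import CVResult
from moodscale.reference import published_weight_table


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert ms.predicted_r2(y, y) == 1.0
        assert ms.rmse(y, y) == 0.0

    def test_test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        assert ms.predicted_r2(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_hand_arithmetic_oracle(self):
        y = np.array([0.0, 0.0, 13.0, 13.0])
        y_hat = np.array([0.0, 13.0, 0.0, 13.0])
        assert ms.rmse(y, y_hat) == pytest.approx(13.0 / np.sqrt(2.0))
        assert ms.predicted_r2(y, y_hat) == pytest.approx(1.0 - (2 * 169) / (4 * 6.5**2))

    def test_constant_truth_gives_missing_r2(self):
        assert np.isnan(ms.predicted_r2(np.ones(4), np.zeros(4)))

    def test_identities(self, rng):
        y = rng.normal(size=30)
        y_hat = rng.normal(size=30)
        assert ms.rmse(y, y_hat) ** 2 == pytest.approx(np.mean((y - y_hat) ** 2))
        assert (ms.predicted_r2(y, y_hat) == 1.0) == bool(np.all(y == y_hat))


class TestCVPlan:
    def test_each_iteration_holds_one_visit_per_subject(self, small_dataset):
        plan = ms.make_cv_plan(small_dataset, K=1, seed=0)
        held = plan.assignments[0]
        assert set(held) == set(small_dataset.subjects)
        for sid, visit in held.items():
            sub = small_dataset.frame[small_dataset.frame["subject_id"] == sid]
            assert visit in set(sub["rating_date"])

    def test_held_out_visit_frequencies_are_uniform(self, small_dataset):
        K = 300
        plan = ms.make_cv_plan(small_dataset, K=K, seed=1)
        sid = small_dataset.subjects[0]
        visits = sorted(
            small_dataset.frame.loc[
                small_dataset.frame["subject_id"] == sid, "rating_date"
            ].unique()
        )
        counts = pd.Series([plan.assignments[i][sid] for i in range(K)]).value_counts()
        observed = [counts.get(pd.Timestamp(v), 0) for v in visits]
        chi2 = sum((o - K / len(visits)) ** 2 / (K / len(visits)) for o in observed)
        assert chi2 < stats.chi2.ppf(0.999, df=len(visits) - 1)

    def test_plan_is_deterministic_given_seed(self, small_dataset):
        a = ms.make_cv_plan(small_dataset, K=3, seed=7)
        b = ms.make_cv_plan(small_dataset, K=3, seed=7)
        assert a.assignments == b.assignments

    def test_subject_with_two_visits_is_rejected(self):
        config = ms.SimConfig(n_subjects=3, n_days=30, n_visits=2, seed=2,
                              missing_rate=0.0, optional_missing_rate=0.0)
        a, r, _ = ms.generate_cohort(config)
        ds = ms.assemble_dataset(a, r, "hdrs_total", "all", "min_rows:1")
        with pytest.raises(ValueError, match="fewer than 3"):
            ms.make_cv_plan(ds, K=2, seed=0)


@pytest.fixture(scope="module")
def cv_result(small_dataset):
    plan = ms.make_cv_plan(small_dataset, K=4, seed=3)
    return (
        plan,
        ms.run_cv(
            ["hierarchical", "pooled_mean", "separate_mean", "pooled_l2"],
            small_dataset,
            plan,
            sampler=ms.SamplerSpec(chains=2, warmup=150, draws=150, seed=5),
            collect_risk=True,
        ),
    )


class TestRunCV:
    def test_one_metric_row_per_model_per_iteration(self, cv_result):
        plan, res = cv_result
        assert res.errors == []
        counts = res.metrics.groupby("model").size()
        assert (counts == plan.K).all()

    def test_train_and_test_rows_are_disjoint(self, small_dataset):
        plan = ms.make_cv_plan(small_dataset, K=3, seed=9)
        from moodscale.evaluation import _fold_masks

        for held in plan.assignments:
            train, test = _fold_masks(small_dataset, held)
            assert not np.any(train & test)
            assert np.all(train | test)
            # the full validity window of a held-out visit moves together
            f = small_dataset.frame
            for sid, visit in held.items():
                window = (f["subject_id"] == sid) & (f["rating_date"] == visit)
                assert test[window.to_numpy()].all()
                assert window.sum() <= 4

    def test_pooled_mean_scores_near_zero_r2(self, cv_result):
        _, res = cv_result
        mean_r2 = res.metrics.loc[res.metrics["model"] == "pooled_mean", "r2"].mean()
        assert mean_r2 <= 0.05

    def test_risk_scores_are_probabilities_with_labels(self, cv_result):
        _, res = cv_result
        assert res.risk is not None
        assert res.risk["score"].between(0, 1).all()
        assert set(res.risk["label"].unique()) <= {0, 1}

    def test_model_failures_recorded_without_aborting(self, small_dataset):
        plan = ms.make_cv_plan(small_dataset, K=2, seed=4)
        frame = small_dataset.frame.copy()
        frame["mood_positive"] = 0.0  # constant feature sinks the Bayesian fit
        ds = ms.preprocess.ModelDataset(
            frame=frame, feature_names=small_dataset.feature_names,
            target_name="hdrs_total", feature_set="all",
            sleep_means=small_dataset.sleep_means,
            population_sleep_mean=small_dataset.population_sleep_mean,
            eligibility=small_dataset.eligibility,
        )
        res = ms.run_cv(["hierarchical", "pooled_mean"], ds, plan,
                        sampler=ms.SamplerSpec(chains=2, warmup=20, draws=20, seed=1))
        assert len(res.errors) == 2
        assert all(e["model"] == "hierarchical" for e in res.errors)
        assert (res.metrics["model"] == "pooled_mean").sum() == 2


class TestCompareModels:
    @staticmethod
    def _cv(scores_a, scores_b):
        rows = [
            {"iteration": i, "model": "A", "target": "t", "feature_set": "all",
             "r2": v, "rmse": 0.0}
            for i, v in enumerate(scores_a)
        ] + [
            {"iteration": i, "model": "B", "target": "t", "feature_set": "all",
             "r2": v, "rmse": 0.0}
            for i, v in enumerate(scores_b)
        ]
        return CVResult(metrics=pd.DataFrame(rows), risk=None, errors=[])

    def test_identical_scores_give_t_zero_p_one(self):
        t, p = ms.compare_models(self._cv([0.5] * 10, [0.5] * 10), "A", "B")
        assert t == 0.0 and p == 1.0

    def test_degenerate_separation(self):
        t, p = ms.compare_models(self._cv([1.0] * 10, [0.0] * 10), "A", "B")
        assert t > 0 and p < 1e-12

    def test_null_simulation_type_i_error(self, rng):
        rejections = 0
        n_sims = 500
        for _ in range(n_sims):
            t, p = ms.compare_models(
                self._cv(rng.normal(size=12), rng.normal(size=12)), "A", "B"
            )
            rejections += p < 0.05
        assert abs(rejections / n_sims - 0.05) < 0.035

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            ms.compare_models(self._cv([1.0], [0.0]), "A", "B")


class TestImportance:
    @pytest.mark.parametrize(
        "target, predictor",
        [
            ("hdrs_total", "mood_negative"),
            ("hdrs_total", "mixed_mood"),
            ("ymrs_total", "mood_positive"),
            ("ymrs_total", "mood_negative"),
        ],
    )
    def test_published_worked_examples_reproduce_printed_importance(self, target, predictor):
        """|t| = |mean|/SD recomputed from the printed posterior mean and SD
        matches the printed importance to two decimals."""
        table = published_weight_table(target).set_index("predictor")
        row = table.loc[predictor]
        assert abs(row["mu_mean"]) / row["mu_sd"] == pytest.approx(row["abs_t"], abs=0.01)

    def test_importance_table_sorted_and_consistent(self, fitted_small):
        table = ms.variable_importance(fitted_small)
        assert list(table["abs_t"]) == sorted(table["abs_t"], reverse=True)
        assert np.allclose(table["abs_t"], np.abs(table["mean"]) / table["sd"])
        assert set(table["predictor"]) == {"intercept", *fitted_small.feature_names}
        assert (table["ci_low"] <= table["ci_high"]).all()

    def test_symmetric_draws_have_negligible_importance(self, rng):
        from moodscale.hier import PosteriorSamples

        mu = rng.standard_normal((2, 2000, 1))
        post = PosteriorSamples(
            kind="pooled", mu=mu, sigma=np.ones((2, 2000)), tau=None,
            alpha=None, beta=None, feature_names=[],
            subject_ids=["A"], target_name="hdrs_total",
        )
        assert ms.variable_importance(post)["abs_t"].item() < 0.1


class TestDescriptiveAssociation:
    def test_perfectly_antimonotone_pair(self):
        table = pd.DataFrame({
            "mood": [-3.0, -1.0, 0.0, 1.0, 3.0],
            "hdrs_total": [30.0, 20.0, 15.0, 10.0, 0.0],
            "ymrs_total": [1.0, 2.0, 3.0, 4.0, 5.0],
        })
        out = ms.descriptive_association(table)
        r_mood_hdrs = out.loc[(out["x"] == "mood") & (out["y"] == "hdrs_total"), "r"].item()
        assert r_mood_hdrs == pytest.approx(-1.0, abs=0.02)

    def test_independent_pairs_have_small_correlation(self, rng):
        table = pd.DataFrame({
            "mood": rng.normal(size=1000),
            "hdrs_total": rng.normal(size=1000),
            "ymrs_total": rng.normal(size=1000),
        })
        out = ms.descriptive_association(table)
        assert (out["r"].abs() < 0.1).all()

    def test_constant_column_reported_missing(self):
        table = pd.DataFrame({
            "mood": [0.0, 0.0, 0.0, 0.0],
            "hdrs_total": [1.0, 2.0, 3.0, 4.0],
            "ymrs_total": [1.0, 3.0, 2.0, 4.0],
        })
        out = ms.descriptive_association(table)
        assert np.isnan(out.loc[out["x"] == "mood", "r"]).all()

    def test_too_few_rows_rejected(self):
        table = pd.DataFrame({"mood": [0.0], "hdrs_total": [1.0], "ymrs_total": [1.0]})
        with pytest.raises(ValueError, match="at least 3"):
            ms.descriptive_association(table)
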