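"""Train/test split, accuracy metrics and model comparison."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fetalweight import (
    DegenerateInputError,
    PregnancyRecord,
    SplitConfig,
    ValidationFailure,
    compare_models,
    medape_by_ga,
    prediction_errors,
    predict_batch,
    split_bernoulli,
    two_sample_t,
)


class TestSplitBernoulli:
    def test_train_fraction_concentrates_around_p(self):
        records = list(range(10_000))
        train, test = split_bernoulli(records, SplitConfig(0.7, seed=11))
        assert 0.69 <= len(train) / len(records) <= 0.71
        assert len(train) + len(test) == len(records)

    def test_same_seed_gives_identical_assignment(self):
        records = list(range(500))
        first = split_bernoulli(records, SplitConfig(0.7, seed=3))
        second = split_bernoulli(records, SplitConfig(0.7, seed=3))
        assert first[0] == second[0] and first[1] == second[1]

    def test_extreme_p_warns_not_raises(self):
        with pytest.warns(UserWarning, match="empty test set"):
            train, test = split_bernoulli(list(range(20)), SplitConfig(0.999999, seed=0))
        assert test == []

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValidationFailure):
            SplitConfig(1.0, seed=0)
        with pytest.raises(ValidationFailure):
            split_bernoulli([], SplitConfig(0.7, seed=0))


class TestPredictionErrors:
    def test_perfect_predictions(self):
        metrics = prediction_errors([3000.0, 2800.0], [3000.0, 2800.0])
        assert metrics["mpe"] == 0.0
        assert metrics["mape"] == 0.0
        assert metrics["medape"] == 0.0
        assert metrics["within10"] == 100.0

    def test_hand_arithmetic_example(self):
        # APEs are 5%, 3%, 4%; errors are +150, -90, -120 g
        metrics = prediction_errors([3000.0, 3000.0, 3000.0], [2850.0, 3090.0, 3120.0])
        assert metrics["mape"] == pytest.approx(4.0)
        assert metrics["medape"] == pytest.approx(4.0)
        assert metrics["mpe"] == pytest.approx(-20.0)

    def test_single_pair_at_the_10pct_boundary(self):
        metrics = prediction_errors([3000.0], [3300.0])
        assert metrics["mpe"] == pytest.approx(-300.0)
        assert metrics["medape"] == pytest.approx(10.0)
        assert metrics["within10"] == 100.0  # boundary inclusive

    def test_even_n_median_interpolates(self):
        metrics = prediction_errors([1000.0] * 4, [990.0, 980.0, 960.0, 940.0])
        # APEs 1, 2, 4, 6 -> median (2 + 4) / 2
        assert metrics["medape"] == pytest.approx(3.0)

    def test_contracts(self):
        with pytest.raises(ValidationFailure):
            prediction_errors([3000.0], [3000.0, 3100.0])
        with pytest.raises(ValidationFailure):
            prediction_errors([0.0], [100.0])

    @settings(derandomize=True, max_examples=25)
    @given(
        st.lists(st.floats(min_value=2000.0, max_value=4500.0), min_size=2, max_size=30),
        st.floats(min_value=0.1, max_value=20.0),
    )
    def test_scale_invariance_of_percentage_metrics(self, abw, factor):
        efw = [a * 0.95 for a in abw]
        base = prediction_errors(abw, efw)
        scaled = prediction_errors([a * factor for a in abw], [e * factor for e in efw])
        assert scaled["mape"] == pytest.approx(base["mape"], rel=1e-9)
        assert scaled["medape"] == pytest.approx(base["medape"], rel=1e-9)
        assert scaled["within10"] == pytest.approx(base["within10"])
        assert scaled["mpe"] == pytest.approx(base["mpe"] * factor, rel=1e-9)

    def test_medape_resists_outlier_inflation(self):
        abw = np.full(9, 3000.0)
        efw = 3000.0 - 3000.0 * np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09])
        base = prediction_errors(abw, efw)["medape"]
        # inflate the largest APE far beyond the median
        efw_out = efw.copy()
        efw_out[-1] = 300.0
        assert prediction_errors(abw, efw_out)["medape"] == pytest.approx(base)


class TestTwoSampleT:
    def test_identical_samples_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = two_sample_t(a, a.copy())
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form_welch_formula(self):
        a = np.array([3.1, 2.8, 3.4, 2.9, 3.0])
        b = np.array([3.6, 3.2, 3.9, 3.8, 3.3])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_hand = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p_hand = 2.0 * stats.t.sf(abs(t_hand), df_hand)
        t, p = two_sample_t(a, b)
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert p == pytest.approx(p_hand, abs=1e-12)

    def test_separated_samples_are_significant(self):
        rng = np.random.default_rng(12)
        t, p = two_sample_t(rng.normal(0, 1, 50), rng.normal(5, 1, 50))
        assert p < 0.0005

    def test_zero_variance_in_both_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])


class TestCompareModels:
    def test_deliberate_bias_shows_in_mpe_and_within10(self, small_cohort):
        records = [r for r in small_cohort if r.abw_g is not None]
        reports = {
            r.model_id: r
            for r in compare_models(["proposed_1", "mod_niswander"], records)
        }
        # mod_niswander under-predicts by hundreds of grams on this process
        assert abs(reports["proposed_1"].mpe) < 100.0
        assert reports["mod_niswander"].mpe > 250.0
        assert reports["mod_niswander"].within10 < reports["proposed_1"].within10

    def test_proposed_models_rank_first_by_medape(self, default_cohort):
        test_records = default_cohort[:1500]
        ids = [
            "proposed_1", "proposed_2", "proposed_3", "proposed_4",
            "johnson_toshach", "risanto_1", "niswander", "santjaka",
            "hadlock_1984", "hadlock_1991",
        ]
        reports = compare_models(ids, test_records, sort_by="medape")
        top4 = {r.model_id for r in reports[:4]}
        assert top4 == {"proposed_1", "proposed_2", "proposed_3", "proposed_4"}

    def test_unbiased_under_correct_specification(self):
        """With ABW centred on the FH backbone (no cohort-mean recentring),
        the one-predictor model's MPE stays within 3 standard errors of
        zero."""
        from fetalweight import GeneratorConfig, generate_cohort

        test_records = generate_cohort(
            GeneratorConfig(n=10_000, seed=606, abw_mean=None)
        )
        report = compare_models(["proposed_1"], test_records, sort_by=None)[0]
        errors_sd = 400.0  # generous bound on the error SD of this process
        assert abs(report.mpe) < 3.0 * errors_sd / math.sqrt(report.n)
        assert report.error_normality_p is not None
        assert report.t_test_p is not None and report.t_test_p > 0.0

    def test_model_without_station_data_reports_n_zero(self):
        records = [
            PregnancyRecord(fh_cm=32.0, ga_weeks=38.0, abw_g=3200.0)
            for _ in range(5)
        ]
        reports = compare_models(["johnson_toshach", "proposed_1"], records, sort_by=None)
        by_id = {r.model_id: r for r in reports}
        assert by_id["johnson_toshach"].n == 0
        assert by_id["johnson_toshach"].note
        assert by_id["proposed_1"].n == 5

    def test_empty_test_set_is_an_error(self):
        with pytest.raises(ValidationFailure):
            compare_models(["proposed_1"], [])


class TestMedapeByGa:
    def test_single_week_stratum_equals_pooled_medape(self):
        records = [
            PregnancyRecord(fh_cm=30.0 + i, ga_weeks=38.4, abw_g=3100.0 + 50 * i)
            for i in range(6)
        ]
        predictions = predict_batch(["proposed_1"], records)
        table = medape_by_ga(records, predictions)
        assert len(table) == 1
        assert table.iloc[0]["ga_week"] == 38
        pooled = prediction_errors(
            [r.abw_g for r in records], predictions["proposed_1"].tolist()
        )["medape"]
        assert table.iloc[0]["medape_pct"] == pytest.approx(pooled)

    def test_two_strata_match_per_stratum_hand_medians(self):
        records = [
            PregnancyRecord(fh_cm=32.0, ga_weeks=37.2, abw_g=3000.0),
            PregnancyRecord(fh_cm=32.0, ga_weeks=37.8, abw_g=3100.0),
            PregnancyRecord(fh_cm=32.0, ga_weeks=40.1, abw_g=3300.0),
            PregnancyRecord(fh_cm=32.0, ga_weeks=40.9, abw_g=3450.0),
        ]
        predictions = predict_batch(["proposed_1"], records)
        efw = predictions["proposed_1"].to_numpy()
        table = medape_by_ga(records, predictions).set_index("ga_week")
        for week, idx in ((37, [0, 1]), (40, [2, 3])):
            abw = np.array([records[i].abw_g for i in idx])
            expected = np.median(np.abs((abw - efw[idx]) / abw) * 100)
            assert table.loc[week, "medape_pct"] == pytest.approx(expected)

    def test_strata_all_finite_nonnegative_on_cohort(self, small_cohort):
        predictions = predict_batch(["proposed_1", "proposed_3"], small_cohort)
        table = medape_by_ga(small_cohort, predictions)
        assert (table["medape_pct"] >= 0).all()
        assert np.isfinite(table["medape_pct"]).all()
        assert set(table["ga_week"]).issubset(set(range(35, 42)))
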