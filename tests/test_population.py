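"""Weighted estimators, age banding and the sex/age summary table."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrescen.data_model import Sex
from fibrescen.population import (
    AGE_BANDS,
    RecommendationSchedule,
    age_band,
    percent_reaching,
    summarize,
    weighted_mean_se,
)
from fibrescen.scenario import HIGHER_FIBRE, IDENTITY, Scenario, compute_intakes
from fibrescen.synthetic import GeneratorConfig, StratumConfig, generate

from conftest import random_dataset


class TestWeightedMeanSE:
    def test_constant_values_have_zero_se(self):
        mean, se = weighted_mean_se([17.2] * 5, [0.5, 1, 2, 3, 0.1])
        assert (mean, se) == (17.2, 0.0)

    def test_single_observation(self):
        assert weighted_mean_se([8.4], [2.0]) == (8.4, 0.0)

    def test_unit_weight_hand_calculation(self):
        # x = {1,2,3}: mean 2, se = sqrt(sum (x-2)^2) / 3 = sqrt(2)/3
        mean, se = weighted_mean_se([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert mean == pytest.approx(2.0)
        assert se == pytest.approx(math.sqrt(2.0) / 3.0)

    def test_weighted_hand_calculation(self):
        # w = {1,3}, x = {10, 20}: mean 17.5; se = sqrt(1*7.5^2 + 9*2.5^2)/4
        mean, se = weighted_mean_se([10.0, 20.0], [1.0, 3.0])
        assert mean == pytest.approx(17.5)
        assert se == pytest.approx(math.sqrt(56.25 + 56.25) / 4.0)

    @pytest.mark.parametrize("values,weights", [([], []), ([1.0], [0.0]), ([1.0], [-1.0])])
    def test_invalid_inputs_rejected(self, values, weights):
        with pytest.raises(ValueError):
            weighted_mean_se(values, weights)


class TestPercentReaching:
    def test_all_above(self):
        assert percent_reaching([31, 40], [1, 1], 30) == (100.0, 0.0)

    def test_all_below(self):
        assert percent_reaching([10, 20], [1, 1], 30) == (0.0, 0.0)

    def test_half_of_hundred_closed_form(self):
        values = [31.0] * 50 + [20.0] * 50
        pct, se = percent_reaching(values, [1.0] * 100, 30.0)
        assert pct == pytest.approx(50.0)
        assert se == pytest.approx(5.0)  # 100*sqrt(0.25/100)

    def test_tie_counts_as_reaching(self):
        pct, _ = percent_reaching([30.0], [1.0], 30.0)
        assert pct == 100.0

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            percent_reaching([1.0], [1.0], 0.0)


class TestAgeBand:
    @pytest.mark.parametrize(
        "age,label",
        [
            (2.0, "Pre-school (1.5-3 years)"),
            (3.99, "Pre-school (1.5-3 years)"),
            (4.0, "Junior School (4-10 years)"),
            (11.0, "Adolescents (11-18 years)"),
            (19.0, "Adults (19-65 years)"),
            (65.9, "Adults (19-65 years)"),
            (66.0, "Older Adults (>65 years)"),
            (101.0, "Older Adults (>65 years)"),
        ],
    )
    def test_band_assignment(self, age, label):
        assert age_band(age) == label

    def test_below_surveyed_range_rejected(self):
        with pytest.raises(ValueError):
            age_band(1.0)


class TestRecommendationSchedule:
    def test_default_thresholds(self):
        sched = RecommendationSchedule()
        assert sched.threshold_for(30.0) == 30.0
        assert sched.threshold_for(3.0) == 15.0
        assert sched.threshold_for(8.0) == 20.0
        assert sched.threshold_for(13.0) == 25.0

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            RecommendationSchedule(bands=((1.5, 10.0, 15.0), (5.0, 20.0, 20.0)))


def _synthetic_dataset(n=500, seed=4):
    strata = (
        StratumConfig(Sex.MALE, "Adults (19-65 years)", n // 2, 19.7, 6.0, (3.3, 2.4, 24.3)),
        StratumConfig(Sex.FEMALE, "Junior School (4-10 years)", n - n // 2, 14.4, 4.0, (2.85, 1.95, 25.2)),
    )
    return generate(GeneratorConfig(strata=strata, seed=seed))


class TestSummarize:
    def test_identity_scenario_columns_match(self, dataset):
        intakes = compute_intakes(dataset, IDENTITY)
        table = summarize(dataset, intakes)
        for row in table.rows:
            if row.current is not None:
                assert row.current == row.scenario

    def test_all_males_above_threshold_reach_100(self):
        ds = _synthetic_dataset(n=40)
        intakes = compute_intakes(ds, IDENTITY)
        # shift every male intake above 30 by replacing results
        import dataclasses
        shifted = [
            dataclasses.replace(r, baseline_g_per_day=31.0, scenario_g_per_day=31.0)
            for r in intakes
        ]
        table = summarize(ds, shifted)
        male = table.sex_rows[0]
        assert male.group_label == "Male"
        assert male.current.pct_reaching == 100.0

    def test_cells_match_group_by_group_oracle(self):
        ds = _synthetic_dataset(n=500)
        intakes = compute_intakes(ds, HIGHER_FIBRE)
        sched = RecommendationSchedule()
        table = summarize(ds, intakes, sched, weighted=True)
        by_id = {r.participant_id: r for r in intakes}

        for row in table.sex_rows + table.age_rows:
            members = [
                p for p in ds.participants
                if (p.sex.value.capitalize() == row.group_label) or (age_band(p.age_years) == row.group_label)
            ]
            assert row.n == len(members)
            if not members:
                continue
            x = np.array([by_id[p.participant_id].baseline_g_per_day for p in members])
            w = np.array([p.survey_weight for p in members])
            thr = np.array([sched.threshold_for(p.age_years) for p in members])
            mean = (w * x).sum() / w.sum()
            se = math.sqrt((w**2 * (x - mean) ** 2).sum()) / w.sum()
            p_hat = (w * (x >= thr)).sum() / w.sum()
            se_pct = 100 * math.sqrt(p_hat * (1 - p_hat) * (w**2).sum()) / w.sum()
            assert row.current.mean_g_per_day == pytest.approx(mean, abs=1e-9)
            assert row.current.se_mean == pytest.approx(se, abs=1e-9)
            assert row.current.pct_reaching == pytest.approx(100 * p_hat, abs=1e-9)
            assert row.current.se_pct == pytest.approx(se_pct, abs=1e-9)

    def test_unit_weights_equal_unweighted(self):
        ds = _synthetic_dataset(n=120)
        # force unit weights
        import dataclasses
        ds.participants = [dataclasses.replace(p, survey_weight=1.0) for p in ds.participants]
        intakes = compute_intakes(ds, HIGHER_FIBRE)
        t1 = summarize(ds, intakes, weighted=True)
        t2 = summarize(ds, intakes, weighted=False)
        for r1, r2 in zip(t1.rows, t2.rows):
            assert r1 == r2

    def test_sex_group_sizes_sum_to_total(self):
        ds = _synthetic_dataset(n=200)
        intakes = compute_intakes(ds, IDENTITY)
        table = summarize(ds, intakes)
        assert sum(r.n for r in table.sex_rows) == len(ds.participants)

    def test_empty_group_emits_n_zero_row(self, dataset, caplog):
        intakes = compute_intakes(dataset, IDENTITY)
        with caplog.at_level("WARNING"):
            table = summarize(dataset, intakes)
        empty = [r for r in table.age_rows if r.n == 0]
        assert empty and all(r.current is None for r in empty)

    def test_group_mean_shift_equals_weighted_mean_delta(self):
        ds = _synthetic_dataset(n=300)
        intakes = compute_intakes(ds, HIGHER_FIBRE)
        table = summarize(ds, intakes, weighted=True)
        by_id = {r.participant_id: r for r in intakes}
        male = table.sex_rows[0]
        members = [p for p in ds.participants if p.sex is Sex.MALE]
        w = np.array([p.survey_weight for p in members])
        d = np.array([by_id[p.participant_id].delta_g_per_day for p in members])
        assert male.scenario.mean_g_per_day - male.current.mean_g_per_day == pytest.approx(
            (w * d).sum() / w.sum(), abs=1e-9
        )


@settings(deadline=None, max_examples=20)
@given(fw=st.floats(1.0, 2.5), fm=st.floats(1.0, 2.0), seed=st.integers(0, 200))
def test_percent_reaching_monotone_under_enrichment(fw, fm, seed):
    ds = random_dataset(np.random.default_rng(seed), n_participants=12, n_entries=40)
    base = summarize(ds, compute_intakes(ds, IDENTITY))
    up = summarize(ds, compute_intakes(ds, Scenario("up", fw, fm, 1.0)))
    for r0, r1 in zip(base.rows, up.rows):
        if r0.current is None:
            continue
        assert r1.scenario.pct_reaching >= r0.current.pct_reaching - 1e-9
        assert r1.scenario.mean_g_per_day >= r0.current.mean_g_per_day - 1e-9
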