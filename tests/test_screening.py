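"""Screening engine: schedule, modality rule, detection, counterfactuals."""

import dataclasses

import numpy as np
import pytest

from tomosim import natural_history as nh
from tomosim.screening import (
    MODE_INTERVAL,
    MODE_SCREEN,
    ScreeningPolicy,
    aggregate,
    build_schedule,
    modality_for,
    screen,
    simulate_cohort,
    simulate_outcomes,
    simulate_woman,
)


class TestSchedule:
    def test_default_biennial_schedule(self, params):
        sched = build_schedule(params)
        assert list(sched) == list(range(50, 75, 2))
        assert len(sched) == 13

    def test_single_round(self, params):
        p = dataclasses.replace(params, screening_end_age=51.0)
        assert list(build_schedule(p)) == [50.0]

    def test_inverted_ages_rejected(self, params):
        p = dataclasses.replace(params, screening_start_age=60.0, screening_end_age=50.0)
        with pytest.raises(ValueError):
            build_schedule(p)


class TestModalityRule:
    def test_scenario1_dense_gets_dbt(self, params):
        pol = ScreeningPolicy("scenario1", dbt_sensitivity=0.8)
        assert modality_for(pol, 3, 2, params).name == "DBT"
        assert modality_for(pol, 4, 2, params).name == "DBT"

    def test_scenario1_non_dense_gets_dm(self, params):
        pol = ScreeningPolicy("scenario1", dbt_sensitivity=0.8)
        assert modality_for(pol, 1, 2, params).name == "DM"
        assert modality_for(pol, 2, 2, params).name == "DM"

    def test_first_round_dbt_flag(self, params):
        pol = ScreeningPolicy(
            "scenario1", dbt_sensitivity=0.8, first_round_dbt_for_density=True
        )
        assert modality_for(pol, 1, 0, params).name == "DBT"
        assert modality_for(pol, 1, 1, params).name == "DM"

    def test_reference_and_scenario2(self, params):
        assert modality_for(ScreeningPolicy("reference"), 4, 0, params).name == "DM"
        assert modality_for(ScreeningPolicy("scenario2"), 1, 0, params).name == "DBT"

    def test_bad_inputs(self, params):
        with pytest.raises(ValueError):
            ScreeningPolicy("scenario3")
        with pytest.raises(ValueError):
            modality_for(ScreeningPolicy("reference"), 5, 0, params)


class TestScreenOperation:
    def test_subthreshold_tumour_never_true_positive(self, params, rng):
        for _ in range(50):
            ev = screen(4.0, params.dm, 2, 60.0, rng, sensitivity_override=1.0)
            assert ev.outcome == "FN"

    def test_detectable_tumour_with_perfect_sensitivity(self, params, rng):
        ev = screen(6.0, params.dm, 2, 60.0, rng, sensitivity_override=1.0)
        assert ev.outcome == "TP"

    def test_false_positive_frequency(self, params, rng):
        n = 200_000
        fp = sum(
            screen(None, params.dm, 2, 60.0, rng).outcome == "FP" for _ in range(n)
        )
        expected = 1 - params.dm.specificity
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(fp / n - expected) < 3 * se

    def test_unattended_screen_delivers_no_dose(self, params, rng):
        ev = screen(None, params.dm, 2, 60.0, rng, attended=False)
        assert not ev.attended and ev.dose == 0.0


class TestCohortSimulation:
    def test_same_seed_bit_identical(self, params):
        pol = ScreeningPolicy("scenario1", dbt_sensitivity=0.9)
        a = simulate_cohort(pol, params, seed=42, n=5_000)
        b = simulate_cohort(pol, params, seed=42, n=5_000)
        for field in ("screen_detected", "interval", "lyg", "false_positives"):
            assert getattr(a, field) == getattr(b, field)
        assert np.array_equal(a.lyg_disc, b.lyg_disc)

    def test_counts_conservation(self, params, rng):
        courses = nh.sample_life_courses(params, rng, 40_000, 13)
        r = aggregate(
            simulate_outcomes(courses, ScreeningPolicy("reference"), params), params
        )
        detected = r.screen_detected + r.interval + r.other_detected
        assert detected + r.undetected == pytest.approx(r.total_tumours)

    def test_zero_participation_equals_counterfactual(self, params, rng):
        p = dataclasses.replace(params, participation_rate=0.0)
        courses = nh.sample_life_courses(p, rng, 20_000, 13)
        out = simulate_outcomes(courses, ScreeningPolicy("reference"), p)
        assert np.array_equal(out.death_screened, out.death_unscreened)
        assert out.lyg.sum() == 0.0
        assert not out.active.any()

    def test_cancer_free_cohort_with_perfect_specificity(self, params, rng):
        p = dataclasses.replace(
            params,
            lifetime_risk=0.0,
            err_per_gy=0.0,
            dm=dataclasses.replace(params.dm, specificity=1.0),
        )
        courses = nh.sample_life_courses(p, rng, 20_000, 13)
        r = aggregate(simulate_outcomes(courses, ScreeningPolicy("reference"), p), p)
        assert r.false_positives == 0
        assert r.screen_detected == r.interval == r.other_detected == 0
        # undiscounted costs are screens times the DM price
        from tomosim.econ import scenario_costs

        assert scenario_costs(r, p, 0) == pytest.approx(
            r.screens_dm * p.dm.cost_per_screen
        )

    def test_mean_lyg_nonnegative_without_radiation(self, params, rng):
        p = dataclasses.replace(params, err_per_gy=0.0)
        courses = nh.sample_life_courses(p, rng, 100_000, 13)
        out = simulate_outcomes(courses, ScreeningPolicy("reference"), p)
        assert np.all(out.lyg >= -1e-9)  # per-woman monotone by construction
        assert out.lyg.mean() > 0

    def test_interval_cancers_follow_attended_negative_round(self, params, rng):
        courses = nh.sample_life_courses(params, rng, 60_000, 13)
        out = simulate_outcomes(courses, ScreeningPolicy("reference"), params)
        sched = out.schedule
        idx = np.flatnonzero(out.mode == MODE_INTERVAL)
        assert idx.size > 0
        for i in idx[:300]:
            dx = out.dx_age[i]
            prev = sched[sched < dx]
            assert prev.size > 0
            r_prev = len(prev) - 1
            assert courses.attendance[i, r_prev]
            assert not out.tp[i, r_prev]
            assert dx - prev[-1] <= params.interval_window + 1e-9


class TestScenarioStructure:
    def test_monotone_in_dbt_sensitivity_with_common_seeds(self, params, rng):
        courses = nh.sample_life_courses(params, rng, 60_000, 13)
        results = [
            aggregate(
                simulate_outcomes(
                    courses, ScreeningPolicy("scenario2", dbt_sensitivity=s), params
                ),
                params,
            )
            for s in (0.65, 0.80, 1.00)
        ]
        screens = [r.screen_detected for r in results]
        intervals = [r.interval for r in results]
        lygs = [r.lyg for r in results]
        assert screens == sorted(screens)
        assert intervals == sorted(intervals, reverse=True)
        assert lygs == sorted(lygs)

    def test_modality_equivalence_degenerate_case(self, params, rng):
        """DBT parameterised identically to DM makes all scenarios agree."""
        p = dataclasses.replace(
            params,
            dbt=dataclasses.replace(
                params.dm, name="DBT"
            ),
        )
        courses = nh.sample_life_courses(p, rng, 30_000, 13)
        results = [
            aggregate(
                simulate_outcomes(
                    courses, ScreeningPolicy(scen, dbt_sensitivity=None), p
                ),
                p,
            )
            for scen in ("reference", "scenario1", "scenario2")
        ]
        for r in results[1:]:
            assert r.screen_detected == results[0].screen_detected
            assert r.interval == results[0].interval
            assert r.lyg == pytest.approx(results[0].lyg)
            assert r.false_positives == results[0].false_positives


class TestScalarApi:
    def test_woman_with_no_onset_gets_tn_events(self, params, rng):
        woman = nh.Woman(id=0, natural_death_age=90.0, onset_age=None, density_latent=0.5)
        out = simulate_woman(woman, ScreeningPolicy("reference"), params, rng)
        assert out.detection_mode == "none"
        assert out.lyg == 0.0
        assert all(ev.outcome in ("TN", "FP") for ev in out.events if ev.attended)

    def test_screen_detected_woman_reports_event_trail(self, params, rng):
        tum = nh.Tumor(onset_age=55.0, initial_diameter=params.aux.initial_diameter_mm,
                       doubling_time=157.0)
        woman = nh.Woman(
            id=1, natural_death_age=95.0, onset_age=55.0, density_latent=0.5, tumor=tum
        )
        # force full attendance and certain detection via prepared courses
        courses = nh.sample_life_courses(params, rng, 1, 13)
        courses.natural_death_age[0] = 95.0
        courses.onset_age[0] = 55.0
        courses.doubling_time[0] = 157.0
        courses.e_self[0] = np.inf
        courses.attendance[0, :] = True
        courses.u_detect[0, :] = 0.0
        courses.u_rad[0] = 0.999999
        out = simulate_woman(woman, ScreeningPolicy("reference"), params, rng, courses)
        assert out.detection_mode == "screen"
        assert out.events[-1].outcome == "TP"
        assert out.diameter_at_detection >= params.dm.detection_threshold
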