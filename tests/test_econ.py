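"""Health economics: discounting, costs, ICERs, threshold search."""

import math

import numpy as np
import pytest
from scipy import integrate

from tomosim.econ import (
    Comparison,
    ComparisonError,
    compare,
    compare_reps,
    discount_value,
    life_years_components,
    threshold_sensitivity,
    woman_costs,
)
from tomosim.params import DiscountScheme
from tomosim.screening import ScreenEvent, WomanOutcome

INTL = DiscountScheme("international", 0.03, 0.03, reference_age=50.0)
FLAT = DiscountScheme("undiscounted", 0.0, 0.0, reference_age=50.0)


def _outcome(events=(), mode="none", dx=None, diam=None, du=90.0, ds=90.0):
    return WomanOutcome(
        detection_mode=mode,
        age_at_detection=dx,
        diameter_at_detection=diam,
        death_age_screened=ds,
        death_age_unscreened=du,
        lyg=ds - du,
        induced_tumour=False,
        events=list(events),
    )


class TestDiscounting:
    def test_value_at_reference_age_unchanged(self):
        assert discount_value(123.4, 50.0, INTL) == 123.4

    def test_zero_rate_unchanged(self):
        assert discount_value(123.4, 80.0, FLAT) == 123.4

    def test_ten_years_at_three_percent(self):
        assert discount_value(100.0, 60.0, INTL) == pytest.approx(
            100.0 / 1.03**10, rel=1e-12
        )

    def test_event_before_reference_age_rejected(self):
        with pytest.raises(ValueError):
            discount_value(1.0, 40.0, INTL)

    def test_discounted_never_exceeds_raw(self):
        for age in (50.0, 55.5, 70.0, 99.0):
            assert discount_value(100.0, age, INTL) <= 100.0


class TestWomanCosts:
    def test_no_events_cost_nothing(self, params):
        assert woman_costs(_outcome(), params, FLAT) == 0.0

    def test_one_attended_dm_screen(self, params):
        ev = ScreenEvent(50.0, "DM", True, "TN", None, 3.0)
        assert woman_costs(_outcome([ev]), params, FLAT) == 64.0

    def test_false_positive_adds_biopsy(self, params):
        ev = ScreenEvent(50.0, "DM", True, "FP", None, 3.0)
        assert woman_costs(_outcome([ev]), params, FLAT) == 64.0 + 176.0

    def test_screen_detected_cancer_priced_by_size(self, params):
        ev = ScreenEvent(60.0, "DM", True, "TP", 15.0, 3.0)
        out = _outcome([ev], mode="screen", dx=60.0, diam=15.0)
        assert woman_costs(out, params, FLAT) == 64.0 + 176.0 + 6438.0

    def test_interval_cancer_gets_biopsy_and_treatment(self, params):
        ev = ScreenEvent(60.0, "DM", True, "FN", 4.0, 3.0)
        out = _outcome([ev], mode="interval", dx=61.0, diam=25.0)
        assert woman_costs(out, params, FLAT) == 64.0 + 176.0 + 7128.0

    def test_unattended_rounds_are_free(self, params):
        ev = ScreenEvent(50.0, "DM", False, "TN", None, 0.0)
        assert woman_costs(_outcome([ev]), params, FLAT) == 0.0


class TestLifeYears:
    def test_equal_death_ages(self):
        assert life_years_components(_outcome(du=85.0, ds=85.0), INTL) == (0.0, 0.0)

    def test_gain_at_reference_age_undiscounted(self):
        raw, disc = life_years_components(_outcome(du=50.0, ds=51.0), FLAT)
        assert (raw, disc) == (1.0, 1.0)

    def test_continuous_stream_integral(self):
        # gain from +30y to +31y after age 50 at 3%
        raw, disc = life_years_components(_outcome(du=80.0, ds=81.0), INTL)
        expected, _ = integrate.quad(lambda t: 1.03**-t, 30.0, 31.0)
        assert raw == pytest.approx(1.0)
        assert disc == pytest.approx(expected, rel=1e-9)

    def test_discrete_approximation_close_to_continuous(self):
        _, cont = life_years_components(_outcome(du=78.3, ds=84.7), INTL)
        _, disc = life_years_components(_outcome(du=78.3, ds=84.7), INTL, discrete=True)
        assert disc == pytest.approx(cont, rel=0.02)


class TestCompare:
    def test_icer_at_wtp_boundary_is_not_cost_effective(self):
        comp = compare_reps([1000.0] * 3, [0.05] * 3, [0.0] * 3, [0.0] * 3, 20_000.0)
        assert comp.icer == pytest.approx(20_000.0)
        assert comp.status == "not_cost_effective"

    def test_dominated(self):
        comp = compare_reps([500.0] * 2, [-2.0] * 2, [0.0] * 2, [0.0] * 2, 20_000.0)
        assert comp.status == "dominated"
        assert math.isnan(comp.icer)

    def test_dominant(self):
        comp = compare_reps([-10.0] * 2, [3.0] * 2, [0.0] * 2, [0.0] * 2, 20_000.0)
        assert comp.status == "dominant"
        assert comp.qualifies

    def test_cost_effective_below_wtp(self):
        comp = compare_reps([1000.0] * 2, [0.1] * 2, [0.0] * 2, [0.0] * 2, 20_000.0)
        assert comp.icer == pytest.approx(10_000.0)
        assert comp.status == "cost_effective"

    def test_mismatched_reps_rejected(self):
        with pytest.raises(ComparisonError):
            compare_reps([1.0, 2.0], [1.0], [0.0, 0.0], [0.0], 20_000.0)

    def test_mismatched_cohort_sizes_rejected(self, params):
        from tomosim.screening import ScreeningPolicy, simulate_cohort

        a = simulate_cohort(ScreeningPolicy("reference"), params, seed=1, n=2_000)
        b = simulate_cohort(ScreeningPolicy("reference"), params, seed=1, n=3_000)
        with pytest.raises(ComparisonError):
            compare(a, b, params)

    def test_delta_method_se_shrinks_with_noise(self):
        rng = np.random.default_rng(0)
        base_c = 1000 + rng.normal(0, 5, 10)
        base_l = 0.1 + rng.normal(0, 0.001, 10)
        tight = compare_reps(base_c, base_l, np.zeros(10), np.zeros(10), 20_000.0)
        loose = compare_reps(
            1000 + rng.normal(0, 50, 10),
            0.1 + rng.normal(0, 0.01, 10),
            np.zeros(10),
            np.zeros(10),
            20_000.0,
        )
        assert tight.se_icer < loose.se_icer

    def test_icer_invariant_to_cohort_rescaling(self, params):
        from tomosim.screening import ScreeningPolicy, simulate_cohort
        from tomosim.econ import scenario_costs

        pol = ScreeningPolicy("scenario2", dbt_sensitivity=1.0)
        r = simulate_cohort(pol, params, seed=5, n=20_000)
        ref = simulate_cohort(ScreeningPolicy("reference"), params, seed=5, n=20_000)
        c1 = compare(r, ref, params)
        # per-10k normalisation means doubling both cohorts' totals changes nothing
        assert c1.icer == pytest.approx(
            (
                scenario_costs(r, params, 1) - scenario_costs(ref, params, 1)
            )
            / (r.lyg_disc[1] - ref.lyg_disc[1]),
            rel=1e-9,
        )


class TestThresholdSensitivity:
    def _grid(self, icers):
        return {
            s: Comparison(
                delta_cost=v * 100.0 if v is not None else 1.0,
                delta_lyg=0.1 if v is not None else -1.0,
                icer=v * 1000.0 if v is not None else math.nan,
                status="dominated" if v is None else (
                    "cost_effective" if v * 1000 < 20000 else "not_cost_effective"
                ),
            )
            for s, v in icers.items()
        }

    def test_published_grid_pattern(self):
        # ICERs in thousands: cost-effective first at 90%
        grid = self._grid({0.85: 24.4, 0.90: 17.3, 0.95: 13.2, 1.00: 11.0})
        assert threshold_sensitivity(grid, 20_000.0) == 0.90

    def test_all_above_wtp(self):
        grid = self._grid({0.9: 31.3, 0.95: 20.8, 1.0: 22.1})
        assert threshold_sensitivity(grid, 20_000.0) is None

    def test_all_dominant_returns_lowest(self):
        grid = {
            s: Comparison(-1.0, 2.0, math.nan, "dominant") for s in (0.65, 0.7, 0.75)
        }
        assert threshold_sensitivity(grid) == 0.65

    def test_dominated_cells_skipped(self):
        grid = self._grid({0.65: None, 0.70: None, 0.90: 15.0})
        assert threshold_sensitivity(grid, 20_000.0) == 0.90
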