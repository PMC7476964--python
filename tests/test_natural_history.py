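"""Natural history: onset, growth, self-detection, survival, induction."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from tomosim import natural_history as nh
from tomosim.natural_history import (
    ONSET_HIGH,
    ONSET_LOW,
    diameter_at,
    age_at_diameter,
    expand_life_table,
    onset_probability,
    sample_life_courses,
    sample_radiation_induction,
    self_detection_delay,
)


def _truncnorm_cdf_70_quadrature(mean, sd):
    """P(onset <= 70 | onset) by direct quadrature of the Normal density."""
    f = lambda x: np.exp(-0.5 * ((x - mean) / sd) ** 2)
    num, _ = integrate.quad(f, ONSET_LOW, 70.0)
    den, _ = integrate.quad(f, ONSET_LOW, ONSET_HIGH)
    return num / den


class TestOnset:
    def test_fraction_with_onset_by_70_matches_lifetime_risk(self, params, rng):
        n = 400_000
        courses = sample_life_courses(params, rng, n, 1)
        frac = float((courses.onset_age <= 70.0).mean())
        se = np.sqrt(0.226 * (1 - 0.226) / n)
        assert abs(frac - params.lifetime_risk) < 3 * se

    def test_conditional_onset_age_distribution_vs_quadrature(self, params, rng):
        q = _truncnorm_cdf_70_quadrature(params.onset_age_mean, params.onset_age_sd)
        courses = sample_life_courses(params, rng, 300_000, 1)
        has = np.isfinite(courses.onset_age)
        frac = float((courses.onset_age[has] <= 70.0).mean())
        se = np.sqrt(q * (1 - q) / has.sum())
        assert abs(frac - q) < 3 * se

    def test_zero_lifetime_risk_means_no_onsets(self, params, rng):
        p = dataclasses.replace(params, lifetime_risk=0.0)
        courses = sample_life_courses(p, rng, 10_000, 1)
        assert not np.isfinite(courses.onset_age).any()

    def test_crude_risk_model_needs_more_onsets_than_net(self, params):
        net = onset_probability(params)
        crude = onset_probability(dataclasses.replace(params, risk_model="crude"))
        assert crude > net


class TestGrowth:
    def test_identity_at_onset(self):
        assert diameter_at(0.1, 157.0, 0.0) == pytest.approx(0.1)

    def test_diameter_doubles_after_three_volume_doublings(self):
        t = 3 * 157.0 / nh.DAYS_PER_YEAR
        assert diameter_at(5.0, 157.0, t) == pytest.approx(10.0, rel=1e-12)

    def test_published_doubling_time_arithmetic(self):
        # 471 days = 3 x 157-day volume doublings: 5 mm -> 10 mm
        assert diameter_at(5.0, 157.0, 471.0 / nh.DAYS_PER_YEAR) == pytest.approx(10.0)

    def test_age_before_onset_rejected(self):
        with pytest.raises(ValueError):
            diameter_at(0.1, 157.0, -0.5)

    @given(
        d0=st.floats(0.001, 4.9),
        dt=st.floats(20.0, 400.0),
        t1=st.floats(0.0, 30.0),
        dt_extra=st.floats(0.01, 10.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_time(self, d0, dt, t1, dt_extra):
        assert diameter_at(d0, dt, t1 + dt_extra) >= diameter_at(d0, dt, t1)

    @given(
        d0=st.floats(0.01, 4.9),
        dt=st.floats(20.0, 400.0),
        t=st.floats(0.0, 20.0),
        k=st.floats(0.1, 5.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_invariance(self, d0, dt, t, k):
        a = diameter_at(d0, k * dt, k * t)
        b = diameter_at(d0, dt, t)
        assert a == pytest.approx(b, rel=1e-9)

    def test_inverse_growth(self):
        tum = nh.Tumor(onset_age=60.0, initial_diameter=0.1, doubling_time=157.0)
        age = age_at_diameter(tum, 20.0)
        assert diameter_at(0.1, 157.0, age - 60.0) == pytest.approx(20.0, rel=1e-9)


class TestSelfDetection:
    def test_zero_hazard_never_detects(self, params):
        aux = dataclasses.replace(params.aux, self_detect_hmax=0.0)
        delay = self_detection_delay(np.array([1.0]), np.array([157.0]), aux)
        assert np.isinf(delay[0])

    def test_step_hazard_detects_at_crossing(self, params):
        # near-step hazard: certain detection as soon as 20 mm is reached
        aux = dataclasses.replace(
            params.aux,
            self_detect_hmax=1e4,
            self_detect_midpoint_mm=20.0,
            self_detect_slope_mm=0.02,
        )
        dt = 157.0
        delay = float(self_detection_delay(np.array([1.0]), np.array([dt]), aux)[0])
        t_cross = (
            3 * dt * np.log2(20.0 / aux.initial_diameter_mm) / nh.DAYS_PER_YEAR
        )
        # the logistic ramp has finite width, so detection can precede the
        # nominal crossing by a few days
        assert delay == pytest.approx(t_cross, abs=7.0 / 365.25)

    def test_larger_exponential_draw_means_later_detection(self, params):
        delays = self_detection_delay(
            np.array([0.1, 1.0, 5.0]), np.full(3, 157.0), params.aux
        )
        assert np.all(np.diff(delays) > 0)


class TestSurvival:
    def test_certain_cure_returns_natural_death(self, params):
        aux = dataclasses.replace(params.aux, cure_max=1.0, cure_midpoint_mm=1e3)
        out = nh.cancer_death_age(
            np.array([60.0]), np.array([10.0]), np.array([88.0]),
            np.array([0.5]), np.array([0.5]), aux,
        )
        assert out[0] == 88.0

    def test_never_exceeds_natural_death(self, params, rng):
        n = 20_000
        out = nh.cancer_death_age(
            np.full(n, 60.0),
            rng.uniform(1, 100, n),
            np.full(n, 85.0),
            rng.uniform(size=n),
            rng.uniform(1e-9, 1, n),
            params.aux,
        )
        assert np.all(out <= 85.0)

    def test_smaller_tumours_live_longer_on_average(self, params, rng):
        n = 100_000
        u_cure = rng.uniform(size=n)
        u_surv = rng.uniform(1e-9, 1, n)
        small = nh.cancer_death_age(
            np.full(n, 60.0), np.full(n, 8.0), np.full(n, 85.0), u_cure, u_surv,
            params.aux,
        )
        large = nh.cancer_death_age(
            np.full(n, 60.0), np.full(n, 45.0), np.full(n, 85.0), u_cure, u_surv,
            params.aux,
        )
        assert small.mean() > large.mean()
        assert np.all(small >= large)  # shared draws: monotone per woman


class TestLifeTable:
    def test_survival_curve_shape(self, params):
        surv = expand_life_table(params.aux.life_table)
        assert surv[0] == 1.0 and surv[-1] == 0.0
        assert np.all(np.diff(surv) <= 0)

    def test_death_ages_plausible(self, params, rng):
        courses = sample_life_courses(params, rng, 50_000, 1)
        d = courses.natural_death_age
        assert np.all((d > 0) & (d <= 110))
        assert 80.0 < d.mean() < 87.0  # life expectancy of a modern female cohort


class TestDensity:
    def test_marginals_match_band_distribution(self, params, rng):
        latent = rng.uniform(size=200_000)
        cats = nh.density_category(latent, 55.0, params)
        freq = np.bincount(cats, minlength=5)[1:] / latent.size
        for got, want in zip(freq, params.density_row(55.0)):
            assert got == pytest.approx(want, abs=3 * np.sqrt(want / latent.size) + 1e-3)

    def test_density_non_increasing_with_age(self, params, rng):
        latent = rng.uniform(size=5_000)
        ages = [35.0, 45.0, 55.0, 65.0, 75.0]
        paths = np.stack([nh.density_category(latent, a, params) for a in ages])
        assert np.all(np.diff(paths, axis=0) <= 0)


class TestRadiationInduction:
    def test_zero_err_never_induces(self, params, rng):
        p = dataclasses.replace(params, err_per_gy=0.0)
        assert sample_radiation_induction([(50.0, 3.0)] * 13, p, rng) is None

    def test_empty_dose_history_never_induces(self, params, rng):
        assert sample_radiation_induction([], params, rng) is None

    def test_monte_carlo_matches_closed_form(self, params):
        # 13 DM screens at 3 mGy: P = 0.226 x 0.51 x 0.039
        doses = [(50.0 + 2 * k, 3.0) for k in range(13)]
        expected = 0.226 * 0.51 * 0.039
        n = 150_000
        rng = np.random.Generator(np.random.PCG64(7))
        hits = sum(
            sample_radiation_induction(doses, params, rng) is not None
            for _ in range(n)
        )
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) < 3 * se

    def test_induced_tumour_respects_latency(self, params):
        rng = np.random.Generator(np.random.PCG64(3))
        doses = [(50.0, 3.0), (52.0, 3.0)]
        for _ in range(3000):
            t = sample_radiation_induction(doses, params, rng)
            if t is not None:
                assert t.induced
                assert t.onset_age >= 50.0 + params.aux.radiation_latency_years
                return
        pytest.fail("no induced tumour observed")


class TestOrderingInvariants:
    def test_onset_detection_death_ordered(self, params, rng):
        from tomosim.screening import ScreeningPolicy, build_schedule, simulate_outcomes

        courses = sample_life_courses(params, rng, 30_000, len(build_schedule(params)))
        out = simulate_outcomes(courses, ScreeningPolicy("reference"), params)
        dx = out.dx_age
        has_dx = np.isfinite(dx)
        spont = has_dx & ~out.dx_induced
        assert np.all(dx[spont] >= courses.onset_age[spont])
        assert np.all(out.death_screened[has_dx] >= dx[has_dx] - 1e-9)
        assert np.all(np.isfinite(out.death_screened))
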